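"""Synthetic paired-scan cohorts for the delta-radiomics pipeline.

The study this pipeline targets (prostate-cancer active surveillance,
27 progressor vs 38 non-progressor target lesions, paired baseline and
final MRI scans) deposited no image data, so every downstream stage is
exercised on simulated cohorts with the statistical structure the
analysis assumes:

* **feature mode** — per-sample baseline texture-feature vectors drawn
  from a correlated Gaussian, with a per-sample shared intercept common
  to both time points (so that delta features cancel sample-level
  offsets) and a class-dependent shift of the informative features in
  progressors only;
* **image mode** — 3D T2WI-like and ADC-like volumes with ellipsoidal
  lesion masks; lesion texture is a correlated noise field whose
  contrast and autocorrelation length drift between time points in
  progressors only, and the ADC-like in-lesion intensity drops at the
  final time point for progressors.

Identical config + seed reproduces cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_feature_cohort",
    "generate_image_cohort",
    "generate_cohort",
    "perturbation_replicate_tables",
    "assign_precise_scores",
]

MODALITIES = ("T2WI", "ADC")
TIME_POINTS = ("base", "final")


@dataclass
class CohortConfig:
    """Study-cohort generation settings.

    Defaults mirror the lesion-level two-class cohort the pipeline is
    designed for: 27 progressors and 38 non-progressors. Effect size is
    the standardised mean difference of informative delta features
    between classes (the delta-noise SD is 1, so ``effect_size`` is in
    SD units).
    """

    n_progressors: int = 27
    n_nonprogressors: int = 38
    mode: Literal["features", "images"] = "features"
    n_features: int = 20
    n_informative: int = 4
    effect_size: float = 1.0
    feature_correlation: float = 0.3
    noise_sd_perturbation: float = 1.0
    volume_shape: tuple[int, int, int] = (28, 28, 16)
    lesion_radius_range: tuple[float, float] = (3.0, 5.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progressors < 1 or self.n_nonprogressors < 1:
            raise ValueError("both classes need at least one sample")
        if self.mode not in ("features", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.feature_correlation < 1:
            raise ValueError("feature_correlation must be in [0, 1)")
        if self.mode == "images":
            r_max = self.lesion_radius_range[1]
            if any(2 * r_max + 2 >= s for s in self.volume_shape):
                raise ValueError("lesion radius range exceeds the voxel grid")

    @property
    def n_samples(self) -> int:
        return self.n_progressors + self.n_nonprogressors


@dataclass
class SyntheticCohort:
    """A generated two-class paired cohort.

    In feature mode ``base``/``final`` are samples x features tables
    and ``ground_truth`` holds the informative column indices. In image
    mode ``volumes[sample_id][modality][time_point]`` is a 3D array and
    ``masks[sample_id][modality]`` the binary lesion mask (shared by
    both time points of a modality).
    """

    config: CohortConfig
    sample_ids: list[str]
    outcome: np.ndarray  # 1 = progressor
    base: pd.DataFrame | None = None
    final: pd.DataFrame | None = None
    ground_truth: np.ndarray | None = None
    volumes: dict | None = None
    masks: dict | None = None
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    acquisition_params: pd.DataFrame | None = None
    precise_scores: np.ndarray | None = None
    lesion_params: pd.DataFrame | None = None


def _outcome_vector(config: CohortConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"S{i:03d}" for i in range(config.n_samples)]
    outcome = np.array(
        [1] * config.n_progressors + [0] * config.n_nonprogressors, dtype=int
    )
    return ids, outcome


def generate_feature_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a paired baseline/final feature cohort.

    Baseline vectors are multivariate Gaussian with equicorrelation
    ``feature_correlation`` plus a per-sample shared intercept. Final
    vectors add unit-SD delta noise and, for progressors only, a shift
    of ``effect_size`` on the informative features.
    """
    if config.mode != "features":
        raise ValueError("config.mode must be 'features'")
    rng = np.random.default_rng(config.seed)
    ids, outcome = _outcome_vector(config)
    n, p = config.n_samples, config.n_features

    rho = config.feature_correlation
    cov = np.full((p, p), rho) + np.eye(p) * (1 - rho)
    core = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    intercept = rng.normal(0.0, 1.0, size=(n, 1))  # cancels in the delta
    informative = np.sort(rng.choice(p, size=config.n_informative,
                                     replace=False))
    shift = np.zeros(p)
    shift[informative] = config.effect_size
    delta_noise = rng.normal(0.0, 1.0, size=(n, p))

    base = core + intercept
    final = base + delta_noise + np.outer(outcome, shift)

    cols = [f"f{i:03d}" for i in range(p)]
    # acquisition scalars, independent of outcome, for the screening stage
    acq = pd.DataFrame(
        {
            "TR": rng.normal(5000, 250, size=n),
            "TE": rng.normal(100, 5, size=n),
        },
        index=ids,
    )
    return SyntheticCohort(
        config=config,
        sample_ids=ids,
        outcome=outcome,
        base=pd.DataFrame(base, index=ids, columns=cols),
        final=pd.DataFrame(final, index=ids, columns=cols),
        ground_truth=informative,
        acquisition_params=acq,
    )


def perturbation_replicate_tables(
    cohort: SyntheticCohort,
    fragile: np.ndarray | list[int] | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Simulate ROI-perturbation replicates of a feature-mode cohort.

    Returns ``{variant: {time_point: table}}`` for the three replicate
    variants (original, opened, closed). Features listed in ``fragile``
    receive independent N(0, noise_sd) perturbation noise in the opened
    and closed replicates, emulating features unstable under mask
    perturbation; all other features are perturbation-invariant up to a
    negligible jitter.
    """
    if cohort.base is None:
        raise ValueError("cohort is not in feature mode")
    cfg = cohort.config
    noise_sd = cfg.noise_sd_perturbation if noise_sd is None else noise_sd
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if fragile is None:
        fragile = []
    fragile = np.asarray(fragile, dtype=int)

    out: dict[str, dict[str, pd.DataFrame]] = {
        "original": {"base": cohort.base.copy(), "final": cohort.final.copy()}
    }
    for variant in ("opened", "closed"):
        tables = {}
        for tp, tab in (("base", cohort.base), ("final", cohort.final)):
            pert = tab.copy()
            # tiny jitter so ICC is defined but ~1 for stable features
            pert += rng.normal(0.0, 1e-3, size=pert.shape)
            if fragile.size:
                pert.iloc[:, fragile] += rng.normal(
                    0.0, noise_sd, size=(len(pert), fragile.size)
                )
            tables[tp] = pert
        out[variant] = tables
    return out


# ---------------------------------------------------------------------------
# image mode


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d2 = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii)
    )
    return d2 <= 1.0


def _texture_field(rng, shape, contrast, corr_len, base_noise=None,
                   shared_frac=0.7):
    """Zero-mean correlated noise field with SD ``contrast``.

    If ``base_noise`` is given, the new white-noise field shares
    ``shared_frac`` of its variance with it (within-pair correlation of
    the underlying texture realisation).
    """
    white = rng.standard_normal(shape)
    if base_noise is not None:
        white = np.sqrt(shared_frac) * base_noise + np.sqrt(
            1 - shared_frac
        ) * white
    smooth = ndimage.gaussian_filter(white, corr_len)
    sd = smooth.std()
    return contrast * smooth / sd if sd > 0 else smooth, white


_MODALITY_BASE = {  # background mean, lesion mean offset, contrast
    "T2WI": dict(bg=400.0, lesion=-120.0, contrast=40.0),
    "ADC": dict(bg=1400.0, lesion=-350.0, contrast=120.0),
}
#: multiplicative drift of lesion texture parameters in progressors at
#: the final time point, and additive drop of in-lesion ADC intensity
PROGRESSOR_DRIFT = dict(contrast=0.6, corr_len=0.5, adc_drop=-250.0)


def generate_image_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate paired T2WI-like / ADC-like volumes with lesion masks."""
    if config.mode != "images":
        raise ValueError("config.mode must be 'images'")
    rng = np.random.default_rng(config.seed)
    ids, outcome = _outcome_vector(config)
    shape = tuple(config.volume_shape)
    r_lo, r_hi = config.lesion_radius_range

    volumes: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    masks: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for sid, y in zip(ids, outcome):
        radii = rng.uniform(r_lo, r_hi, size=3)
        centre = [
            rng.uniform(r + 1, s - r - 2) for r, s in zip(radii, shape)
        ]
        mask = _ellipsoid_mask(shape, centre, radii)
        corr_len = rng.uniform(0.8, 1.4)
        volumes[sid] = {}
        masks[sid] = {}
        for mod in MODALITIES:
            pars = _MODALITY_BASE[mod]
            contrast0 = pars["contrast"] * rng.uniform(0.8, 1.2)
            lesion_mean0 = pars["bg"] + pars["lesion"]
            bg = pars["bg"] + 0.15 * pars["contrast"] * ndimage.gaussian_filter(
                rng.standard_normal(shape), 3.0
            ) / 0.05
            vols = {}
            base_white = None
            for tp in TIME_POINTS:
                drift = y == 1 and tp == "final"
                contrast = contrast0 * (
                    1 + PROGRESSOR_DRIFT["contrast"] if drift else 1
                )
                clen = corr_len * (
                    1 + PROGRESSOR_DRIFT["corr_len"] if drift else 1
                )
                lesion_mean = lesion_mean0 + (
                    PROGRESSOR_DRIFT["adc_drop"]
                    if drift and mod == "ADC"
                    else 0.0
                )
                tex, white = _texture_field(
                    rng, shape, contrast, clen, base_noise=base_white
                )
                if base_white is None:
                    base_white = white
                vol = bg.copy()
                vol[mask] = lesion_mean + tex[mask]
                vol += rng.normal(0.0, 2.0, size=shape)  # acquisition noise
                vols[tp] = vol
                rows.append(
                    dict(sample_id=sid, modality=mod, time_point=tp,
                         contrast=contrast, corr_len=clen,
                         lesion_mean=lesion_mean)
                )
            volumes[sid][mod] = vols
            masks[sid][mod] = mask

    acq = pd.DataFrame(
        {
            "TR": rng.normal(5000, 250, size=len(ids)),
            "TE": rng.normal(100, 5, size=len(ids)),
        },
        index=ids,
    )
    return SyntheticCohort(
        config=config,
        sample_ids=ids,
        outcome=outcome,
        volumes=volumes,
        masks=masks,
        acquisition_params=acq,
        lesion_params=pd.DataFrame(rows),
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Dispatch on ``config.mode``."""
    if config.mode == "features":
        return generate_feature_cohort(config)
    return generate_image_cohort(config)


def assign_precise_scores(
    cohort: SyntheticCohort, reader_error_rate: float = 0.2,
    seed: int | None = None
) -> SyntheticCohort:
    """Simulate serial-MRI change scores (5-point scale) for the cohort.

    A correct reading gives progressors a score in {4, 5} and
    non-progressors a score in {1, 2, 3}; with probability
    ``reader_error_rate`` the score is drawn from the opposite pool.
    Stands in for the prospective radiologist scoring of real cohorts.
    """
    if not 0 <= reader_error_rate <= 1:
        raise ValueError("reader_error_rate must be in [0, 1]")
    rng = np.random.default_rng(
        cohort.config.seed + 2 if seed is None else seed
    )
    scores = np.empty(len(cohort.sample_ids), dtype=int)
    flip = rng.random(len(scores)) < reader_error_rate
    for i, y in enumerate(cohort.outcome):
        as_progressor = bool(y) != bool(flip[i])
        scores[i] = rng.choice([4, 5] if as_progressor else [1, 2, 3])
    cohort.precise_scores = scores
    return cohort
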