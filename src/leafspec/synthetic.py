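"""Seeded synthetic leaf spectra and correlated trait tables.

Emulates the structure a VIS-NIR-SWIR leaf calibration study assumes: six
correlated leaf traits sampled per environment group (nitrogen-deficient
field, fertilised field, greenhouse), and for each plant nine replicate
reflectance scans (3 leaves x 3 positions) on the 350-2500 nm 1-nm grid.

A spectrum is built as a smooth continuum — low visible shoulder, logistic
red edge near 700-750 nm, NIR plateau, gentle SWIR decline — minus Gaussian
absorption dips: pigment dips near 430/660 nm scaled by chlorophyll, water
dips at 970/1240/1450/1900 nm scaled by leaf water content, and weak dry
matter dips in 2000-2400 nm scaled by nitrogen (faintly by P and K). Noise
is zero-mean Gaussian, with an elevated standard deviation below 450 nm where
real instruments are noisy. All reflectance is clamped to [0.001, 1.0].

This is an empirical generator, not a radiative-transfer model; absolute
magnitudes are not meant to match any particular instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import RAW_GRID_NM, Spectrum, SpectraMatrix, TraitTable, TRAIT_NAMES

__all__ = [
    "GROUPS",
    "SyntheticConfig",
    "default_config",
    "generate_traits",
    "traits_to_spectrum",
    "generate_dataset",
]

GROUPS = ("FieldMinusN", "FieldPlusN", "Greenhouse")

# Group trait means: CHL/N ordered Greenhouse > Field+N > Field-N; the other
# traits shift only mildly between environments.
_DEFAULT_MEANS = {
    #            CHL    LWC   SLA    N     P     K
    "FieldMinusN": (300.0, 77.0, 16.0, 2.2, 0.22, 1.60),
    "FieldPlusN": (420.0, 79.5, 14.0, 3.0, 0.28, 1.80),
    "Greenhouse": (520.0, 81.0, 15.0, 3.6, 0.30, 1.90),
}
_DEFAULT_SDS = (80.0, 3.0, 2.5, 0.45, 0.05, 0.30)

# Pairwise trait correlations (order CHL, LWC, SLA, N, P, K). Signs encode the
# consistently observed relations: CHL-N and N-P positive, CHL-SLA negative,
# LWC-SLA and LWC-K positive. Positive definite (smallest eigenvalue 0.159).
_DEFAULT_CORR = (
    (1.00, 0.00, -0.55, 0.75, 0.35, 0.00),
    (0.00, 1.00, 0.50, 0.00, 0.00, 0.50),
    (-0.55, 0.50, 1.00, -0.35, 0.00, 0.20),
    (0.75, 0.00, -0.35, 1.00, 0.60, 0.10),
    (0.35, 0.00, 0.00, 0.60, 1.00, 0.10),
    (0.00, 0.50, 0.20, 0.10, 0.10, 1.00),
)

# Gaussian absorption dips: (center nm, width nm, driving trait, strength at
# the trait's normalisation scale). Pigments absorb in the blue and red; water
# at its overtone/combination bands; dry matter (N-rich proteins plus faint
# P/K confounds) in the long SWIR.
_DEFAULT_FEATURES = (
    (430.0, 45.0, "CHL", 0.090),
    (660.0, 60.0, "CHL", 0.100),
    (970.0, 45.0, "LWC", 0.040),
    (1240.0, 60.0, "LWC", 0.070),
    (1450.0, 90.0, "LWC", 0.280),
    (1900.0, 110.0, "LWC", 0.320),
    (2100.0, 80.0, "N", 0.060),
    (2300.0, 60.0, "N", 0.050),
    (2150.0, 70.0, "P", 0.003),
    (1350.0, 70.0, "K", 0.008),
)

# Trait value that maps to feature strength 1.0 (normalisation denominators).
_TRAIT_SCALE = {"CHL": 500.0, "LWC": 100.0, "SLA": 15.0, "N": 4.0, "P": 0.35, "K": 2.0}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the standard study conditions."""

    n_samples_per_group: int = 150
    groups: tuple[str, ...] = GROUPS
    seed: int = 0
    trait_means: dict = field(default_factory=lambda: {g: dict(zip(TRAIT_NAMES, m)) for g, m in _DEFAULT_MEANS.items()})
    trait_sds: dict = field(default_factory=lambda: dict(zip(TRAIT_NAMES, _DEFAULT_SDS)))
    trait_correlation: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_CORR))
    absorption_features: tuple = _DEFAULT_FEATURES
    noise_sd_vis_edge: float = 0.012  # reflectance units, bands < 450 nm
    noise_sd_main: float = 0.004  # reflectance units
    structural_sd: float = 0.02  # per-plant continuum scale sd (leaf structure)
    within_leaf_sd: float = 0.01  # per-scan continuum scale sd
    nuisance_sd: float = 0.006  # amplitude sd of per-plant smooth spectral bumps
    nuisance_n_bumps: int = 8  # unmodelled-constituent bumps per plant
    replicates_per_sample: int = 9

    def __post_init__(self) -> None:
        self.trait_correlation = np.asarray(self.trait_correlation, dtype=float)
        C = self.trait_correlation
        if C.shape != (len(TRAIT_NAMES),) * 2:
            raise ValueError("trait_correlation must be 6x6")
        if not np.allclose(C, C.T):
            raise ValueError("trait_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_correlation must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("trait_correlation must be positive semi-definite")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least one replicate per sample")
        if self.noise_sd_vis_edge < 0 or self.noise_sd_main < 0:
            raise ValueError("noise sds must be non-negative")
        for center, width, trait, strength in self.absorption_features:
            if width <= 0:
                raise ValueError(f"non-positive width for feature at {center} nm")
            if trait not in TRAIT_NAMES:
                raise ValueError(f"unknown driving trait {trait!r}")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **overrides)


def generate_traits(config: SyntheticConfig, rng: np.random.Generator | None = None) -> TraitTable:
    """Sample the six traits per group from a correlated Gaussian, then clip.

    Within each group the trait vector is multivariate normal with the group
    mean, the shared per-trait sds and the shared correlation matrix. Values
    are clipped to physical ranges (LWC to [0, 100], everything else to >= 0).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sds = np.array([config.trait_sds[t] for t in TRAIT_NAMES])
    cov = config.trait_correlation * np.outer(sds, sds)
    rows, ids = [], []
    for group in config.groups:
        means = np.array([config.trait_means[group][t] for t in TRAIT_NAMES])
        # svd factorization: handles the degenerate (zero-sd) case too
        draws = rng.multivariate_normal(means, cov, size=config.n_samples_per_group)
        for i, draw in enumerate(draws):
            ids.append(f"{group}_{i + 1:03d}")
            rows.append(draw)
    values = np.vstack(rows)
    df = pd.DataFrame(values, index=ids, columns=list(TRAIT_NAMES))
    df["LWC"] = df["LWC"].clip(0.0, 100.0)
    for col in ("CHL", "N", "P", "K"):
        df[col] = df[col].clip(lower=0.0)
    df["SLA"] = df["SLA"].clip(lower=1e-3)
    df["group"] = [i.rsplit("_", 1)[0] for i in ids]
    return TraitTable(df)


def _continuum(wl: np.ndarray) -> np.ndarray:
    # visible shoulder -> logistic red edge -> NIR plateau -> gentle SWIR decline
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 712.0) / 22.0))
    swir_decline = 1.0 / (1.0 + np.exp(-(wl - 1700.0) / 250.0))
    return 0.15 + 0.38 * red_edge - 0.10 * swir_decline


def traits_to_spectrum(
    traits: dict | pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    replicate_label: str = "leaf2_tip",
    noise: bool = True,
    continuum_scale: float = 1.0,
    baseline: np.ndarray | None = None,
) -> Spectrum:
    """Render one scan from a trait vector.

    With ``noise=False`` (and default ``continuum_scale``/``baseline``) the
    spectrum is a deterministic function of the traits. ``continuum_scale``
    models smooth brightness variation (leaf structure); ``baseline`` is an
    additive smooth deviation shared by a plant's replicates (unmodelled
    constituents), added to the continuum before the absorption dips.
    """
    wl = RAW_GRID_NM
    refl = _continuum(wl) * continuum_scale
    if baseline is not None:
        refl = refl + baseline
    for center, width, trait, strength in config.absorption_features:
        level = float(traits[trait]) / _TRAIT_SCALE[trait]
        refl = refl - strength * level * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if noise:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sd = np.where(wl < 450.0, config.noise_sd_vis_edge, config.noise_sd_main)
        refl = refl + rng.normal(0.0, 1.0, size=wl.size) * sd
    refl = np.clip(refl, 0.001, 1.0)
    return Spectrum(wl, refl, sample_id=sample_id, replicate_label=replicate_label)


def generate_dataset(config: SyntheticConfig) -> tuple[list[Spectrum], TraitTable]:
    """Generate replicate scans plus the matching trait table, reproducibly.

    Replicates of a plant share its trait vector and differ only by fresh
    noise and a small smooth continuum perturbation per scan.
    """
    rng = np.random.default_rng(config.seed)
    table = generate_traits(config, rng=rng)
    leaves = (2, 3, 4)
    positions = ("tip", "middle", "base")
    labels = [f"leaf{lf}_{pos}" for lf in leaves for pos in positions]
    wl = RAW_GRID_NM
    scans: list[Spectrum] = []
    for sid, row in table.data.iterrows():
        # Per-plant components shared by all nine replicates, so they do NOT
        # average out: a structural brightness factor (leaf thickness /
        # surface roughness) and a smooth additive nuisance curve standing in
        # for unmodelled constituents that vary between plants.
        plant_scale = 1.0 + rng.normal(0.0, config.structural_sd)
        baseline = np.zeros(wl.size)
        for _ in range(config.nuisance_n_bumps):
            center = rng.uniform(450.0, 2450.0)
            width = rng.uniform(60.0, 250.0)
            amp = rng.normal(0.0, config.nuisance_sd)
            baseline += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        for r in range(config.replicates_per_sample):
            label = labels[r] if r < len(labels) else f"rep{r + 1}"
            scale = plant_scale * (1.0 + rng.normal(0.0, config.within_leaf_sd))
            scans.append(
                traits_to_spectrum(
                    row, config, rng=rng, sample_id=sid,
                    replicate_label=label, continuum_scale=scale,
                    baseline=baseline,
                )
            )
    return scans, table


def generate_matrix(config: SyntheticConfig) -> tuple[SpectraMatrix, TraitTable]:
    """Convenience: generate, then average replicates into a sample matrix."""
    from .spectra_io import average_replicates

    scans, table = generate_dataset(config)
    return average_replicates(scans), table
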