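"""Synthetic GDM/NGT dual-omics cohorts with planted, recoverable effects.

The generator emulates the structure of a two-group pregnancy cohort profiled
by shotgun metagenomics (species-level relative abundances) and untargeted
serum metabolomics, with oral-glucose-tolerance-test (OGTT) outcomes:

* latent species log-abundances are multivariate normal with group-specific
  block-correlation structure (a Gaussian copula over the designated
  top-abundance taxa), giving the co-occurrence network stage planted modules;
* group mean shifts on chosen taxa plant differential abundance;
* abundances are exponentiated, zero-inflated for rare taxa, and closed to
  compositions, reproducing the sparse compositional character of
  MetaPhlAn-style profiles;
* metabolites are noisy linear read-outs of latent species log-abundances,
  so species -> metabolite -> pathway chains are recoverable;
* 1-h OGTT glucose is driven by a planted log-ratio balance of taxa, and the
  GDM label is assigned by the standard IADPSG diagnostic thresholds applied
  to the generated OGTT values.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dualomics.core_io import AbundanceTable, MetaboliteTable, SampleMetadata
from dualomics.errors import ConfigError, ValidationError

# IADPSG one-step 75-g OGTT diagnostic thresholds, mg/dL.
FPG_THRESHOLD = 92.0
G1H_THRESHOLD = 180.0
G2H_THRESHOLD = 153.0

MGDL_PER_MMOL = 18.016  # molar mass conversion for glucose


@dataclass
class CorrelationBlock:
    """A block of taxa sharing a within-block latent correlation per group."""

    taxa: list[int]
    rho_gdm: float
    rho_ngt: float

    def __post_init__(self) -> None:
        for rho in (self.rho_gdm, self.rho_ngt):
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"block correlation {rho} outside (-1, 1)")


@dataclass
class BalanceSpec:
    """Planted log-ratio balance linked linearly to 1-h OGTT glucose."""

    numerator: list[int]
    denominator: list[int]
    coefficient: float = 12.0  # mg/dL glucose per unit balance score
    noise_sd: float = 8.0  # mg/dL

    def __post_init__(self) -> None:
        if set(self.numerator) & set(self.denominator):
            raise ConfigError("balance numerator and denominator overlap")
        if not self.numerator or not self.denominator:
            raise ConfigError("balance sides must be non-empty")


@dataclass
class MetaboliteSpec:
    """One metabolite: linear couplings to species plus Gaussian noise."""

    name: str
    couplings: list[tuple[int, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    pathways: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohortConfig:
    """Full description of a synthetic cohort; see module docstring.

    ``diff_taxa`` maps taxon index -> log2 fold effect added to the GDM
    group's latent mean.  ``zero_inflation_prob`` applies to taxa with index
    >= ``n_zero_safe`` only, keeping the top-abundance block (the network
    stage's universe) dense.
    """

    n_gdm: int = 50
    n_ngt: int = 54
    n_species: int = 300
    diff_taxa: dict[int, float] = field(default_factory=dict)
    module_spec: list[CorrelationBlock] = field(default_factory=list)
    balance_spec: BalanceSpec | None = None
    metab_spec: list[MetaboliteSpec] = field(default_factory=list)
    pathway_sizes: dict[str, int] = field(default_factory=dict)
    zero_inflation_prob: float = 0.3
    n_zero_safe: int = 50
    log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ConfigError("zero_inflation_prob must be in [0, 1]")
        referenced: set[int] = set(self.diff_taxa)
        for block in self.module_spec:
            referenced |= set(block.taxa)
        if self.balance_spec is not None:
            referenced |= set(self.balance_spec.numerator)
            referenced |= set(self.balance_spec.denominator)
        for m in self.metab_spec:
            referenced |= {i for i, _ in m.couplings}
        bad = [i for i in referenced if not 0 <= i < self.n_species]
        if bad:
            raise ConfigError(f"taxon indices out of range: {sorted(bad)}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, keyed by taxon/metabolite names."""

    diff_taxa: dict[str, float]
    balance_numerator: list[str]
    balance_denominator: list[str]
    balance_coefficient: float
    balance_scores: pd.Series
    correlation_gdm: np.ndarray
    correlation_ngt: np.ndarray
    coupling: pd.DataFrame
    design_group: pd.Series


def default_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Cohort configuration mirroring the study regime.

    Two groups of 50 and 54 samples, 300 species, ten differential taxa at
    |log2 FC| = 1.5 inside the top-abundance stratum, one correlation module
    denser in the GDM group (within-block rho 0.6 vs 0.2) and one shared
    module, a 2-vs-2 taxon balance driving 1-h OGTT glucose, and a metabolite
    panel in which three planted pathways are read out by three measured
    metabolites each -- the "dopamine-pathway" chain couples its metabolites
    to differential driver species.
    """
    diff_up = [5, 12, 24, 36, 48]
    diff_down = [8, 18, 30, 42, 55]
    diff = {i: 1.5 for i in diff_up} | {i: -1.5 for i in diff_down}
    modules = [
        CorrelationBlock(taxa=list(range(0, 8)), rho_gdm=0.6, rho_ngt=0.2),
        CorrelationBlock(taxa=list(range(20, 28)), rho_gdm=0.45, rho_ngt=0.45),
    ]
    balance = BalanceSpec(numerator=[12, 24], denominator=[18, 42])
    metab: list[MetaboliteSpec] = []
    # driver pathway: metabolites coupled to differential species 8 and 18
    for j, drivers in enumerate([[(8, 1.0)], [(8, 0.8), (18, 0.4)], [(18, 1.0)]]):
        metab.append(
            MetaboliteSpec(
                name=f"dopamine_metab_{j}",
                couplings=drivers,
                noise_sd=0.5,
                pathways=["dopaminergic synapse"],
            )
        )
    for j in range(3):
        metab.append(
            MetaboliteSpec(
                name=f"betalain_metab_{j}",
                couplings=[(20 + j, 0.6)],
                noise_sd=0.5,
                pathways=["betalain biosynthesis"],
            )
        )
    for j in range(3):
        metab.append(
            MetaboliteSpec(
                name=f"alkaloid_metab_{j}",
                couplings=[],
                noise_sd=1.0,
                pathways=["isoquinoline alkaloid biosynthesis"],
            )
        )
    for j in range(21):
        metab.append(
            MetaboliteSpec(name=f"noise_metab_{j:02d}", couplings=[], noise_sd=1.0)
        )
    sizes = {
        "dopaminergic synapse": 6,
        "betalain biosynthesis": 5,
        "isoquinoline alkaloid biosynthesis": 6,
    }
    cfg = dict(
        n_gdm=50,
        n_ngt=54,
        n_species=300,
        diff_taxa=diff,
        module_spec=modules,
        balance_spec=balance,
        metab_spec=metab,
        pathway_sizes=sizes,
        seed=seed,
    )
    cfg.update(overrides)
    return SyntheticCohortConfig(**cfg)


# ---------------------------------------------------------------------------
# Clinical helper functions
# ---------------------------------------------------------------------------


def diagnose_gdm(fpg: float, g1h: float, g2h: float) -> str:
    """IADPSG one-step diagnosis from a 75-g OGTT (all values mg/dL).

    GDM when fasting glucose >= 92, 1-h glucose >= 180, or 2-h glucose >= 153
    mg/dL; otherwise NGT.
    """
    vals = (fpg, g1h, g2h)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise ValidationError("OGTT diagnosis requires all three glucose values")
    if any(v < 0 for v in vals):
        raise ValidationError("glucose values must be non-negative")
    if fpg >= FPG_THRESHOLD or g1h >= G1H_THRESHOLD or g2h >= G2H_THRESHOLD:
        return "GDM"
    return "NGT"


def homa_ir(fasting_glucose_mmol: float, fasting_insulin_uiu: float) -> float:
    """HOMA1-IR insulin-resistance index: glucose [mmol/L] x insulin [uIU/mL] / 22.5."""
    if fasting_glucose_mmol <= 0 or fasting_insulin_uiu <= 0:
        raise ValidationError("HOMA-IR inputs must be positive")
    return fasting_glucose_mmol * fasting_insulin_uiu / 22.5


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _group_correlation(config: SyntheticCohortConfig, group: str) -> np.ndarray:
    corr = np.eye(config.n_species)
    for block in config.module_spec:
        rho = block.rho_gdm if group == "GDM" else block.rho_ngt
        idx = np.asarray(block.taxa)
        corr[np.ix_(idx, idx)] = rho
        corr[idx, idx] = 1.0
    return corr


def _balance_from_logs(
    logs: np.ndarray, num: list[int], den: list[int]
) -> np.ndarray:
    k1, k2 = len(num), len(den)
    coef = np.sqrt(k1 * k2 / (k1 + k2))
    return coef * (logs[:, num].mean(axis=1) - logs[:, den].mean(axis=1))


# Two-group clinical surrogates (mean, sd) echoing a GDM-vs-NGT cohort.
_CLINICAL = {
    "fasting_insulin": ((7.41, 5.0), (2.86, 1.5)),  # uIU/mL, sd tightened
    "hba1c": ((5.17, 0.44), (5.00, 0.31)),  # %
    "bmi_prepregnancy": ((20.19, 3.90), (17.11, 1.81)),  # kg/m2
    "tg": ((2.32, 0.74), (1.97, 0.63)),  # mmol/L
    "neutrophil_count": ((7.89, 1.89), (6.98, 1.95)),  # 1e9/L
    "neutrophil_pct": ((76.0, 5.0), (73.0, 5.0)),  # %
    "lymphocyte_pct": ((18.0, 4.0), (21.0, 4.0)),  # %
}

# OGTT generation parameters (mg/dL): fasting and 2-h glucose separate the
# design groups directly; 1-h glucose carries the planted balance signal.
_FPG = {"GDM": (100.0, 6.0), "NGT": (80.0, 4.0)}
_G2H = {"GDM": (148.0, 14.0), "NGT": (118.0, 11.0)}
_G1H_INTERCEPT = 150.0


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[AbundanceTable, MetaboliteTable, SampleMetadata, SyntheticTruth]:
    """Generate one cohort; bit-identical for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_gdm + config.n_ngt
    p = config.n_species
    design = np.array(["GDM"] * config.n_gdm + ["NGT"] * config.n_ngt)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    taxa = [f"Species_{i + 1:03d}" for i in range(p)]

    # latent log-abundances: decreasing base means so taxon index tracks rank
    base_mu = np.linspace(4.0, -4.0, p)
    chol = {}
    for g in ("GDM", "NGT"):
        corr = _group_correlation(config, g)
        try:
            chol[g] = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError(
                f"{g} block-correlation matrix is not positive definite"
            ) from exc
    z = rng.standard_normal((n, p))
    logs = np.empty((n, p))
    for g in ("GDM", "NGT"):
        mask = design == g
        logs[mask] = z[mask] @ chol[g].T
    logs = base_mu + config.log_sd * logs
    for idx, log2_effect in config.diff_taxa.items():
        logs[design == "GDM", idx] += log2_effect * np.log(2.0)

    # metabolites read out the latent logs before zero inflation
    metab_names = [m.name for m in config.metab_spec]
    coupling = pd.DataFrame(0.0, index=metab_names, columns=taxa)
    metab_vals = np.empty((n, len(config.metab_spec)))
    for j, spec in enumerate(config.metab_spec):
        signal = np.zeros(n)
        for idx, w in spec.couplings:
            signal += w * logs[:, idx]
            coupling.iloc[j, idx] = w
        signal = signal + spec.noise_sd * rng.standard_normal(n)
        # shift to strictly positive instrument-style units
        span = signal.max() - signal.min()
        metab_vals[:, j] = signal - signal.min() + 0.05 * (span + 1.0)
    pathway_map = {
        m.name: set(m.pathways) for m in config.metab_spec if m.pathways
    }

    # OGTT outcomes and diagnosis
    if config.balance_spec is not None:
        bal = config.balance_spec
        b_scores = _balance_from_logs(logs, bal.numerator, bal.denominator)
        g1h = (
            _G1H_INTERCEPT
            + bal.coefficient * b_scores
            + bal.noise_sd * rng.standard_normal(n)
        )
    else:
        b_scores = np.zeros(n)
        g1h = _G1H_INTERCEPT + 14.0 * rng.standard_normal(n)
    fpg = np.empty(n)
    g2h = np.empty(n)
    for g in ("GDM", "NGT"):
        mask = design == g
        fpg[mask] = _FPG[g][0] + _FPG[g][1] * rng.standard_normal(mask.sum())
        g2h[mask] = _G2H[g][0] + _G2H[g][1] * rng.standard_normal(mask.sum())
    fpg = np.clip(fpg, 40.0, None)
    g1h = np.clip(g1h, 40.0, None)
    g2h = np.clip(g2h, 40.0, None)
    label = np.array([diagnose_gdm(f, a, b) for f, a, b in zip(fpg, g1h, g2h)])

    # clinical covariates from two-group surrogates
    clin = {}
    for col, (gdm_ms, ngt_ms) in _CLINICAL.items():
        vals = np.empty(n)
        for g, (mu, sd) in (("GDM", gdm_ms), ("NGT", ngt_ms)):
            mask = design == g
            vals[mask] = mu + sd * rng.standard_normal(mask.sum())
        clin[col] = np.clip(vals, 0.1, None)
    homa = np.array(
        [
            homa_ir(gluc / MGDL_PER_MMOL, ins)
            for gluc, ins in zip(fpg, clin["fasting_insulin"])
        ]
    )

    # zero-inflate rare taxa after exponentiation, then close per sample
    abund = np.exp(logs)
    if config.zero_inflation_prob > 0 and config.n_zero_safe < p:
        mask = rng.random((n, p)) < config.zero_inflation_prob
        mask[:, : config.n_zero_safe] = False
        abund[mask] = 0.0
    abund = 100.0 * abund / abund.sum(axis=1, keepdims=True)

    abundance = AbundanceTable(
        pd.DataFrame(abund, index=sample_ids, columns=taxa),
        closure=100.0,
        rank="species",
    )
    metabolites = MetaboliteTable(
        pd.DataFrame(metab_vals, index=sample_ids, columns=metab_names),
        pathway_map=pathway_map,
        pathway_sizes=dict(config.pathway_sizes),
    )
    meta = pd.DataFrame(
        {
            "group": label,
            "ogtt_glucose_0h": fpg,
            "ogtt_glucose_1h": g1h,
            "ogtt_glucose_2h": g2h,
            "homa_ir": homa,
            **clin,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta, glucose_unit="mg/dL")

    truth = SyntheticTruth(
        diff_taxa={taxa[i]: fc for i, fc in config.diff_taxa.items()},
        balance_numerator=(
            [taxa[i] for i in config.balance_spec.numerator]
            if config.balance_spec
            else []
        ),
        balance_denominator=(
            [taxa[i] for i in config.balance_spec.denominator]
            if config.balance_spec
            else []
        ),
        balance_coefficient=(
            config.balance_spec.coefficient if config.balance_spec else 0.0
        ),
        balance_scores=pd.Series(b_scores, index=sample_ids),
        correlation_gdm=_group_correlation(config, "GDM"),
        correlation_ngt=_group_correlation(config, "NGT"),
        coupling=coupling,
        design_group=pd.Series(design, index=sample_ids),
    )
    return abundance, metabolites, metadata, truth
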