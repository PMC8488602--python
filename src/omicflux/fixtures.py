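"""Self-contained synthetic inputs for the full pipeline.

Provides a small, hand-balanced photoautotroph network (photon-driven
ATP/NADPH production, carbon fixation, three nitrogen assimilation
routes, sulfate/iron uptake, a biomass sink, ATP maintenance and a pair
of redundant parallel pathways that exercise the 2-norm tie-break),
RPKM-like transcript tables with three control replicates and planted
per-condition effects, the packaged per-condition exchange-bound table,
and the growth-rate vector available for the regression subset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fba import ConditionSpec
from .gpr import truncate_gene_ids
from .model import MetabolicModel

__all__ = [
    "FixtureConfig",
    "CONDITIONS",
    "CONTROL_NAME",
    "GROWTH_RATE_CONDITIONS",
    "make_toy_model",
    "make_synthetic_transcriptome",
    "builtin_condition_bounds",
    "builtin_growth_rates",
    "default_condition_effects",
]

#: the 23 experimental growth conditions, in sweep order
CONDITIONS = [
    "Darkoxic", "Darkanoxic", "Highlight", "OD04", "OD10", "OD30", "OD50",
    "lowO2", "lowCO2", "Nlim", "Slim", "Plim", "Felim", "Nitrate", "Ammonia",
    "Urea", "Heatshock", "T22", "T30", "Oxstress", "Mixotrophic", "Lowsalt",
    "Highsalt",
]
CONTROL_NAME = "Standardcontrol"

#: conditions with usable growth rates (control handled separately)
GROWTH_RATE_CONDITIONS = [
    "Nlim", "Slim", "Plim", "Nitrate", "Ammonia", "Urea", "T22", "T30",
    "Mixotrophic", "Lowsalt", "Highsalt",
]

_GROWTH_RATES = [
    ("Standard Control", 0.075),
    ("N-limited", 0.046153846),
    ("S-limited", 0.05),
    ("P-limited", 0.035294118),
    ("Nitrate", 0.173286795),
    ("Ammonia", 0.266595069),
    ("Urea", 0.266595069),
    ("22C", 0.038659794),
    ("30C", 0.068807339),
    ("Mixotrophic", 0.089285714),
    ("Low salt", 0.076530612),
    ("High salt", 0.027777778),
]

# designed network dimensions
_N_METS = 15
_N_RXNS = 22
_N_GENES = 14


@dataclass
class FixtureConfig:
    """Parameters of the synthetic transcriptome (and the fixed network).

    The toy network topology is curated, so the size fields are fixed
    at the designed values and only validated. ``effect_sizes`` maps
    condition -> gene -> multiplicative expression shift; conditions or
    genes not listed default to a factor of 1. ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal noise.
    """

    n_metabolites: int = _N_METS
    n_reactions: int = _N_RXNS
    n_genes: int = _N_GENES
    n_conditions: int = len(CONDITIONS)
    seed: int = 0
    noise_cv: float = 0.1
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_rpkm: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_reactions", "n_genes", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.n_metabolites, self.n_reactions, self.n_genes) != (
            _N_METS,
            _N_RXNS,
            _N_GENES,
        ):
            raise ValueError(
                "the toy network topology is fixed at "
                f"({_N_METS} metabolites, {_N_RXNS} reactions, {_N_GENES} genes)"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


# reaction table: (id, name, equation, lb, ub, grRule, raw subsystem)
_REACTIONS = [
    ("EX_PHOTON", "Photon exchange", "photon_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_CO2", "CO2 exchange", "co2_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_O2", "O2 exchange", "o2_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_GLYC", "Glycerol exchange", "glyc_c ->", 0, 1000, "", "Exchange Reaction"),
    ("EX_NO3", "Nitrate exchange", "no3_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_NH4", "Ammonium exchange", "nh4_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_UREA", "Urea exchange", "urea_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_SO4", "Sulfate exchange", "so4_c ->", -1000, 1000, "", "Exchange Reaction"),
    ("EX_FE", "Iron exchange", "fe_c ->", -1000, 1000, "", "Exchange Reaction"),
    (
        "PSII", "photosystem II reaction",
        "2 photon_c -> o2_c + atp_c", 0, 1000,
        "(psbA1.1 or psbA2.1) and psbO.1", "Photosynthesis",
    ),
    (
        "PSI", "Photosystem I Reaction (cytochrome c6)",
        "2 photon_c -> nadph_c", 0, 1000,
        "psaA.1 and psaB.1", "Photosynthesis",
    ),
    (
        "CBB", "CO2 fixation (Calvin cycle)",
        "co2_c + 3 atp_c + 2 nadph_c -> cfix_c", 0, 1000,
        "rbcL.1 and rbcS.1", "Carbon fixation",
    ),
    (
        "GLYCD", "Glycerol catabolism",
        "glyc_c + o2_c -> cfix_c + 2 atp_c", 0, 1000,
        "glpK.1", "Carbohydrate Metabolism",
    ),
    (
        "NO3A", "Nitrate assimilation",
        "no3_c + nadph_c -> nsrc_c", 0, 1000,
        "narB.1", "Amino Acid Metabolisms",
    ),
    (
        "NH4A", "Ammonium assimilation",
        "nh4_c + 0.5 atp_c -> nsrc_c", 0, 1000,
        "glnA.1", "Amino Acid Metabolisms",
    ),
    (
        "UREA1", "Urease",
        "urea_c -> 2 nsrc_c + co2_c", 0, 1000,
        "ureC.1", "Amino Acid Metabolisms",
    ),
    (
        "SULFA", "Sulfate assimilation",
        "so4_c + atp_c + nadph_c -> ssrc_c", 0, 1000,
        "cysH.1", "Lipid and Cell Wall Metabolism",
    ),
    (
        "PAR1", "Precursor synthesis A",
        "cfix_c + atp_c -> prec_c", 0, 1000,
        "parA.1", "Glycolysis",
    ),
    (
        "PAR2", "Precursor synthesis B",
        "cfix_c + atp_c -> prec_c", 0, 1000,
        "parB.1", "Glycolysis",
    ),
    (
        "BIOMASS", "Biomass synthesis (carbon limited)",
        "prec_c + 0.5 nsrc_c + 0.05 ssrc_c + 0.005 fe_c + 2 atp_c ->",
        0, 1000, "", "Biomass",
    ),
    ("ATPM", "ATP maintenance requirment", "atp_c ->", 0, 1000, "", ""),
    ("DM_O2", "O2 dissipation sink", "o2_c ->", 0, 1000, "", "Other"),
]

_GENES = [
    "psbA1.1", "psbA2.1", "psbO.1", "psaA.1", "psaB.1", "rbcL.1", "rbcS.1",
    "glpK.1", "narB.1", "glnA.1", "ureC.1", "cysH.1", "parA.1", "parB.1",
]


def make_toy_model(config: FixtureConfig | None = None) -> MetabolicModel:
    """Build the curated toy network (deterministic; no randomness).

    The model ships with raw subsystem annotations so the curation steps
    (synonym normalization, 'and'-splitting) have real work to do, and
    with all-zero objective indicators, mirroring a freshly loaded model.
    """
    from .model import parse_equation

    if config is None:
        config = FixtureConfig()
    coeff_maps = [parse_equation(eq) for _, _, eq, *_ in _REACTIONS]
    mets = sorted({m for cm in coeff_maps for m in cm})
    stoich = np.zeros((len(mets), len(_REACTIONS)))
    mpos = {m: i for i, m in enumerate(mets)}
    for j, cm in enumerate(coeff_maps):
        for m, c in cm.items():
            stoich[mpos[m], j] = c
    return MetabolicModel(
        stoich=stoich,
        lb=np.array([r[3] for r in _REACTIONS], dtype=float),
        ub=np.array([r[4] for r in _REACTIONS], dtype=float),
        rxns=[r[0] for r in _REACTIONS],
        rxn_names=[r[1] for r in _REACTIONS],
        mets=mets,
        genes=list(_GENES),
        gr_rules=[r[5] for r in _REACTIONS],
        subsystems=[[r[6]] for r in _REACTIONS],
    )


def default_condition_effects() -> dict[str, dict[str, float]]:
    """Planted multiplicative expression shifts per condition.

    Dark conditions silence the photosystem genes, high light induces
    them, mixotrophy induces glycerol catabolism (a 4x up-shift),
    nutrient limitation represses the matching assimilation gene, and
    the alternative nitrogen sources induce their pathways.
    """
    return {
        "Darkoxic": {"psbA1": 0.2, "psbA2": 0.2, "psaA": 0.2, "psaB": 0.2},
        "Darkanoxic": {"psbA1": 0.15, "psbA2": 0.15, "psaA": 0.15, "psaB": 0.15},
        "Highlight": {"psbA1": 3.0, "psbA2": 2.0, "psaA": 2.0},
        "lowCO2": {"rbcL": 0.5, "rbcS": 0.5},
        "Nlim": {"narB": 0.3, "glnA": 1.5},
        "Slim": {"cysH": 0.3},
        "Felim": {"psaA": 0.6},
        "Nitrate": {"narB": 2.0},
        "Ammonia": {"glnA": 2.5, "narB": 0.4},
        "Urea": {"ureC": 3.0, "narB": 0.4},
        "Mixotrophic": {"glpK": 4.0},
        "Highsalt": {"psbO": 0.7},
    }


def make_synthetic_transcriptome(
    model: MetabolicModel, config: FixtureConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two RPKM-like tables mirroring the two-dataset layout.

    Each table carries a gene-id column (truncated ids plus a few genes
    absent from the model), a COG category column, three standard
    control replicate columns and one column per condition. Values are
    baseline x condition effect x multiplicative lognormal noise. The
    first table holds the first 16 conditions, the second the remaining
    7, each normalized against its own control replicates.
    """
    if config is None:
        config = FixtureConfig()
    rng = np.random.default_rng(config.seed)
    effects = config.effect_sizes or default_condition_effects()

    gene_ids = truncate_gene_ids(model.genes) + ["extA", "extB", "extC", "extD"]
    lo, hi = config.baseline_rpkm
    baseline = rng.uniform(lo, hi, size=len(gene_ids))
    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    def noise(size):
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)

    cogs = rng.choice(list("CEFGHJKLMOPT"), size=len(gene_ids))

    def build(conditions: list[str]) -> pd.DataFrame:
        data = {"gene_id": gene_ids, "COGCategory": cogs}
        for rep in range(1, 4):
            data[f"control_{rep}"] = baseline * noise(len(gene_ids))
        for cond in conditions:
            eff = np.array([effects.get(cond, {}).get(g, 1.0) for g in gene_ids])
            data[cond] = baseline * eff * noise(len(gene_ids))
        return pd.DataFrame(data)

    return build(CONDITIONS[:16]), build(CONDITIONS[16:])


def builtin_condition_bounds() -> list[ConditionSpec]:
    """The packaged per-condition exchange-bound table (24 specs).

    Every spec carries the full set of exchange bounds (defaults merged
    with per-condition overrides); the control is last, matching the
    row order of the flux matrices.
    """
    ref = importlib.resources.files("omicflux.data") / "condition_bounds.yaml"
    cfg = yaml.safe_load(ref.read_text())
    specs = []
    for entry in cfg["conditions"]:
        lb = dict(cfg["defaults"]["lb"])
        lb.update(entry.get("lb") or {})
        ub = dict(cfg["defaults"]["ub"])
        ub.update(entry.get("ub") or {})
        specs.append(ConditionSpec(name=entry["name"], lb_overrides=lb, ub_overrides=ub))
    return specs


def builtin_growth_rates() -> tuple[list[str], np.ndarray]:
    """Names and values of the 12 usable growth rates, control first."""
    names = [n for n, _ in _GROWTH_RATES]
    values = np.array([v for _, v in _GROWTH_RATES])
    return names, values
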