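"""Genome-scale metabolic model container and curation utilities.

The :class:`MetabolicModel` holds a stoichiometric matrix together with
per-reaction bounds, boolean gene-protein-reaction (GPR) rule strings,
pathway (subsystem) annotations and a pair of binary objective-indicator
vectors ``f`` (primary objective) and ``g`` (secondary objective).

Models can be read from SBML (via COBRApy) or from a plain-text
"toy-table" layout (``reactions.tsv`` + ``genes.tsv``) defined by this
package so that small fixture networks need no SBML tooling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicModel",
    "ObjectivePair",
    "SubsystemIndex",
    "read_model",
    "write_toy_table",
    "normalize_subsystem_names",
    "split_multi_subsystems",
    "set_objective_pair",
    "build_subsystem_index",
    "to_cobra",
]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


@dataclass
class MetabolicModel:
    """Stoichiometric model with objective indicators and annotations.

    Attributes
    ----------
    stoich:
        Metabolites x reactions stoichiometric coefficient matrix.
    lb, ub:
        Per-reaction flux bounds (mmol/gDW/h).
    rxns, rxn_names:
        Reaction identifiers and human-readable names.
    mets:
        Metabolite identifiers.
    genes:
        Gene identifiers as they appear in the model (may carry a
        trailing ``.<digit>`` transcript suffix).
    gr_rules:
        Per-reaction boolean gene rule strings (``and``/``or``/parens);
        empty string for reactions without a gene association.
    subsystems:
        Per-reaction list of subsystem names (one or more per reaction).
    f, g:
        Binary indicator vectors selecting the primary and secondary
        objective reaction (each contains at most one 1).
    """

    stoich: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    rxns: list[str]
    rxn_names: list[str]
    mets: list[str]
    genes: list[str]
    gr_rules: list[str]
    subsystems: list[list[str]]
    f: np.ndarray = field(default=None)  # type: ignore[assignment]
    g: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n = self.n_reactions
        if self.f is None:
            self.f = np.zeros(n, dtype=int)
        if self.g is None:
            self.g = np.zeros(n, dtype=int)
        self.f = np.asarray(self.f, dtype=int)
        self.g = np.asarray(self.g, dtype=int)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.rxns)

    @property
    def n_metabolites(self) -> int:
        return len(self.mets)

    @property
    def n_genes(self) -> int:
        """Number of gene variables (the dimension of expression vectors)."""
        return len(self.genes)

    def validate(self) -> None:
        n = self.n_reactions
        for name, vec in (
            ("lb", self.lb),
            ("ub", self.ub),
            ("rxn_names", self.rxn_names),
            ("gr_rules", self.gr_rules),
            ("subsystems", self.subsystems),
            ("f", self.f),
            ("g", self.g),
        ):
            if len(vec) != n:
                raise ValueError(f"length of {name} ({len(vec)}) != reaction count ({n})")
        if self.stoich.shape != (self.n_metabolites, n):
            raise ValueError(
                f"stoichiometric matrix shape {self.stoich.shape} does not match "
                f"(metabolites, reactions) = ({self.n_metabolites}, {n})"
            )
        if np.any(self.lb > self.ub):
            bad = [self.rxns[i] for i in np.nonzero(self.lb > self.ub)[0]]
            raise ValueError(f"lb > ub for reactions {bad}")
        for name, vec in (("f", self.f), ("g", self.g)):
            if int(vec.sum()) > 1 or not np.isin(vec, (0, 1)).all():
                raise ValueError(f"{name} must be binary with at most one 1")

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            stoich=self.stoich.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            rxns=list(self.rxns),
            rxn_names=list(self.rxn_names),
            mets=list(self.mets),
            genes=list(self.genes),
            gr_rules=list(self.gr_rules),
            subsystems=[list(s) for s in self.subsystems],
            f=self.f.copy(),
            g=self.g.copy(),
        )

    def reaction_index(self, name: str) -> int:
        """Resolve a reaction id or name to its (unique) index."""
        hits = [i for i, r in enumerate(self.rxns) if r == name]
        if not hits:
            hits = [i for i, r in enumerate(self.rxn_names) if r == name]
        if not hits:
            raise KeyError(f"unknown reaction {name!r}")
        if len(hits) > 1:
            raise KeyError(f"reaction {name!r} is ambiguous (indices {hits})")
        return hits[0]


@dataclass(frozen=True)
class ObjectivePair:
    """Indices of the primary (f) and secondary (g) objective reactions."""

    primary_index: int
    secondary_index: int
    M: int = 2  # number of stacked objectives

    def __post_init__(self) -> None:
        if self.primary_index == self.secondary_index:
            raise ValueError("primary and secondary objectives must differ")

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "ObjectivePair":
        fi = np.nonzero(model.f)[0]
        gi = np.nonzero(model.g)[0]
        if len(fi) != 1 or len(gi) != 1:
            raise ValueError("model does not carry a complete objective pair (f, g)")
        return cls(int(fi[0]), int(gi[0]))


@dataclass
class SubsystemIndex:
    """Reaction membership lists per unique subsystem.

    A reaction annotated with k subsystems appears in k membership
    lists, mirroring how multi-classified reactions are counted once per
    pathway during pathway-level aggregation.
    """

    names: list[str]
    membership: list[list[int]]
    cardinality: np.ndarray

    def members(self, name: str) -> list[int]:
        return self.membership[self.names.index(name)]


# ---------------------------------------------------------------------------
# Subsystem curation
# ---------------------------------------------------------------------------

#: Synonym table merging inconsistently annotated subsystem names.
SUBSYSTEM_SYNONYMS = {
    "Amino Acid Metabolisms": "Amino acid metabolism",
    "Amino Acid Metabolism": "Amino acid metabolism",
    "Exchange Reaction": "Exchange",
    "Lipid and Cell Wall Metabolism": "Lipid metabolism and Cell wall",
    "None": "Unassigned",
    "Other": "Unassigned",
    "": "Unassigned",
}

#: Names that legitimately contain the word "and"; rewritten with "&"
#: before splitting so they survive as single subsystems.
PROTECTED_AND_NAMES = {
    "Metabolism of terpenoids and polyketides": "Metabolism of terpenoids & polyketides",
    "Metabolism of cofactors and vitamins": "Metabolism of cofactors & vitamins",
    "Coenzymes and prosthetic groups": "Coenzymes & prosthetic groups",
    "Glycan biosynthesis and metabolism": "Glycan biosynthesis & metabolism",
    "Nucleotides and nucleic acids": "Nucleotides & nucleic acids",
}

_AND_SPLIT = re.compile(r"\band\b", flags=re.IGNORECASE)


def normalize_subsystem_names(model: MetabolicModel) -> MetabolicModel:
    """Apply the subsystem synonym table; empty annotations become 'Unassigned'.

    Idempotent: a second application changes nothing.
    """
    out = model.copy()
    new = []
    for entry in out.subsystems:
        names = [SUBSYSTEM_SYNONYMS.get(s.strip(), s.strip()) for s in entry]
        names = [n if n else "Unassigned" for n in names]
        if not names:
            names = ["Unassigned"]
        new.append(names)
    out.subsystems = new
    return out


def split_multi_subsystems(model: MetabolicModel) -> MetabolicModel:
    """Split subsystem strings that pack several pathways joined by 'and'.

    Protected names (those that genuinely contain 'and') are first
    rewritten with '&'. The split matches 'and' as a whole word,
    case-insensitively, so names such as 'Island' are never cut. Empty
    fragments are dropped; a reaction left with no name gets
    ['Unassigned'].
    """
    out = model.copy()
    new = []
    for entry in out.subsystems:
        names: list[str] = []
        for s in entry:
            s = PROTECTED_AND_NAMES.get(s, s)
            for frag in _AND_SPLIT.split(s):
                frag = frag.strip()
                if frag:
                    names.append(frag)
        if not names:
            names = ["Unassigned"]
        new.append(names)
    out.subsystems = new
    return out


def set_objective_pair(
    model: MetabolicModel, primary_name: str, secondary_name: str
) -> MetabolicModel:
    """Select the primary/secondary objective reactions by id or name.

    Previous indicator settings are cleared, so re-selection always
    leaves exactly one 1 in each of ``f`` and ``g``.
    """
    pi = model.reaction_index(primary_name)
    si = model.reaction_index(secondary_name)
    if pi == si:
        raise ValueError("primary and secondary objectives must be distinct reactions")
    out = model.copy()
    out.f = np.zeros(out.n_reactions, dtype=int)
    out.g = np.zeros(out.n_reactions, dtype=int)
    out.f[pi] = 1
    out.g[si] = 1
    return out


def build_subsystem_index(model: MetabolicModel) -> SubsystemIndex:
    """Index reactions by subsystem, honoring multi-membership."""
    names = sorted({s for entry in model.subsystems for s in entry})
    membership = [[] for _ in names]
    pos = {n: i for i, n in enumerate(names)}
    for rix, entry in enumerate(model.subsystems):
        for s in entry:
            membership[pos[s]].append(rix)
    cardinality = np.array([len(m) for m in membership], dtype=int)
    return SubsystemIndex(names=names, membership=membership, cardinality=cardinality)


# ---------------------------------------------------------------------------
# Toy-table format (reactions.tsv + genes.tsv)
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"\s*(<=>|->|<-)\s*")


def _parse_side(side: str) -> list[tuple[float, str]]:
    terms = []
    side = side.strip()
    if not side:
        return terms
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise ModelParseError(f"bad coefficient in term {term!r}") from exc
            met = parts[1]
        else:
            raise ModelParseError(f"cannot parse reaction term {term!r}")
        terms.append((coef, met))
    return terms


def parse_equation(eq: str) -> dict[str, float]:
    """Parse 'a + 2 b -> c' style equations into {metabolite: coefficient}."""
    pieces = _ARROW.split(eq)
    if len(pieces) != 3:
        raise ModelParseError(f"equation {eq!r} must contain exactly one arrow")
    left, arrow, right = pieces
    coeffs: dict[str, float] = {}
    lhs, rhs = (right, left) if arrow == "<-" else (left, right)
    for coef, met in _parse_side(lhs):
        coeffs[met] = coeffs.get(met, 0.0) - coef
    for coef, met in _parse_side(rhs):
        coeffs[met] = coeffs.get(met, 0.0) + coef
    return coeffs


def format_equation(coeffs: dict[str, float]) -> str:
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items
        )

    lhs = [(m, c) for m, c in coeffs.items() if c < 0]
    rhs = [(m, c) for m, c in coeffs.items() if c > 0]
    return f"{side(lhs)} -> {side(rhs)}"


def _read_toy_table(path: Path) -> MetabolicModel:
    rfile = path / "reactions.tsv"
    gfile = path / "genes.tsv"
    if not rfile.exists():
        raise ModelParseError(f"missing {rfile}")
    try:
        rtab = pd.read_csv(rfile, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ModelParseError(f"cannot parse {rfile}: {exc}") from exc
    required = {"id", "name", "equation", "lb", "ub", "grRule", "subsystems"}
    missing = required - set(rtab.columns)
    if missing:
        raise ModelParseError(f"{rfile} lacks columns {sorted(missing)}")

    genes: list[str] = []
    if gfile.exists():
        gtab = pd.read_csv(gfile, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in gtab.columns:
            raise ModelParseError(f"{gfile} lacks an 'id' column")
        genes = list(gtab["id"])

    rxns = list(rtab["id"])
    rxn_names = list(rtab["name"])
    try:
        lb = rtab["lb"].astype(float).to_numpy()
        ub = rtab["ub"].astype(float).to_numpy()
    except ValueError as exc:
        raise ModelParseError(f"non-numeric bound in {rfile}: {exc}") from exc
    gr_rules = list(rtab["grRule"])
    subsystems = [
        [s for s in entry.split(";") if s != ""] or [""] for entry in rtab["subsystems"]
    ]

    coeff_maps = [parse_equation(eq) for eq in rtab["equation"]]
    mets = sorted({m for cm in coeff_maps for m in cm})
    stoich = np.zeros((len(mets), len(rxns)))
    mpos = {m: i for i, m in enumerate(mets)}
    for j, cm in enumerate(coeff_maps):
        for m, c in cm.items():
            stoich[mpos[m], j] = c

    if not genes:
        # infer gene list from rules so the model is self-contained
        from .gpr import genes_in_rule

        seen: dict[str, None] = {}
        for rule in gr_rules:
            for gid in genes_in_rule(rule):
                seen.setdefault(gid)
        genes = list(seen)

    return MetabolicModel(
        stoich=stoich,
        lb=lb,
        ub=ub,
        rxns=rxns,
        rxn_names=rxn_names,
        mets=mets,
        genes=genes,
        gr_rules=gr_rules,
        subsystems=subsystems,
    )


def write_toy_table(model: MetabolicModel, path: str | Path) -> Path:
    """Write a model as the plain-text toy-table layout; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for j in range(model.n_reactions):
        coeffs = {
            model.mets[i]: model.stoich[i, j]
            for i in range(model.n_metabolites)
            if model.stoich[i, j] != 0
        }
        rows.append(
            {
                "id": model.rxns[j],
                "name": model.rxn_names[j],
                "equation": format_equation(coeffs),
                "lb": repr(float(model.lb[j])),
                "ub": repr(float(model.ub[j])),
                "grRule": model.gr_rules[j],
                "subsystems": ";".join(model.subsystems[j]),
            }
        )
    pd.DataFrame(rows).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({"id": model.genes}).to_csv(path / "genes.tsv", sep="\t", index=False)
    return path


def _read_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelParseError(f"cannot parse SBML file {path}: {exc}") from exc

    mets = [m.id for m in cm.metabolites]
    rxns = [r.id for r in cm.reactions]
    mpos = {m: i for i, m in enumerate(mets)}
    stoich = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            stoich[mpos[met.id], j] = coef
    subsystems = []
    for r in cm.reactions:
        sub = getattr(r, "subsystem", "") or ""
        subsystems.append([s for s in sub.split(";") if s] or [""])
    return MetabolicModel(
        stoich=stoich,
        lb=np.array([r.lower_bound for r in cm.reactions], dtype=float),
        ub=np.array([r.upper_bound for r in cm.reactions], dtype=float),
        rxns=rxns,
        rxn_names=[r.name or r.id for r in cm.reactions],
        mets=mets,
        genes=[g.id for g in cm.genes],
        gr_rules=[r.gene_reaction_rule or "" for r in cm.reactions],
        subsystems=subsystems,
    )


def read_model(path: str | Path, format: str = "toy-table") -> MetabolicModel:
    """Read a metabolic model from SBML or the toy-table layout.

    Freshly loaded models carry all-zero objective indicators and empty
    strings for missing gene rules.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "toy-table":
        return _read_toy_table(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def to_cobra(model: MetabolicModel):
    """Convert to a COBRApy model (used for SBML export and cross-checks)."""
    import cobra

    cm = cobra.Model("omicflux")
    cmets = {m: cobra.Metabolite(m, compartment="c") for m in model.mets}
    for j, rid in enumerate(model.rxns):
        rxn = cobra.Reaction(rid, name=model.rxn_names[j])
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {
                cmets[model.mets[i]]: model.stoich[i, j]
                for i in range(model.n_metabolites)
                if model.stoich[i, j] != 0
            }
        )
        if model.gr_rules[j]:
            rxn.gene_reaction_rule = model.gr_rules[j]
        rxn.subsystem = ";".join(model.subsystems[j])
    return cm
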