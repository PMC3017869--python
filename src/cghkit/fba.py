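"""Stoichiometric models and flux balance analysis.

A metabolic network is read from a reaction table (id, formula, EC,
semicolon-separated genes) whose formula dialect is
``coef? MET (+ coef? MET)* (= | ->) coef? MET (+ coef? MET)*`` with
"=" marking reversible and "->" irreversible reactions; a formula with
one empty side (e.g. ``GLC =``) is an exchange reaction across the
system boundary. Reactions whose every associated gene is absent by
CGH are removed (a single surviving isozyme keeps the reaction), and
the maximal biomass synthesis rate on a defined medium is found by
linear programming: max c.v subject to S.v = 0 and per-reaction flux
bounds, with medium uptake limits applied as exchange lower bounds.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

DEFAULT_BOUND = 1000.0
ZERO_GROWTH_TOL = 1e-9   # objective below this is reported as exactly 0
GROWTH_THRESHOLD = 1e-6  # grow / no-grow cutoff for phenotype screens


class ModelError(ValueError):
    pass


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite -> coefficient (negative consumed)
    reversible: bool
    lower: float
    upper: float
    genes: list[str] = field(default_factory=list)
    ec: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")


def parse_formula(formula: str) -> tuple[dict[str, float], bool]:
    """Parse one reaction formula; returns (stoichiometry, reversible)."""
    if "->" in formula:
        sep, reversible = "->", False
    elif "=" in formula:
        sep, reversible = "=", True
    else:
        raise ModelError(f"no '=' or '->' separator in formula: {formula!r}")
    left_s, right_s = formula.split(sep, 1)

    def side(text: str, sign: float) -> dict[str, float]:
        text = text.strip()
        if not text:
            return {}
        terms = {}
        for raw in text.split("+"):
            raw = raw.strip()
            m = _TERM_RE.match(raw)
            if not m:
                raise ModelError(f"unparseable term {raw!r} in formula: {formula!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            terms[met] = terms.get(met, 0.0) + sign * coef
        return terms

    stoich = side(left_s, -1.0)
    for met, coef in side(right_s, +1.0).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelError(f"formula has no net stoichiometry: {formula!r}")
    return stoich, reversible


def make_reaction(rid: str, formula: str, ec: str = "",
                  genes: list[str] | None = None) -> Reaction:
    stoich, reversible = parse_formula(formula)
    lower = -DEFAULT_BOUND if reversible else 0.0
    return Reaction(id=rid, stoichiometry=stoich, reversible=reversible,
                    lower=lower, upper=DEFAULT_BOUND, genes=genes or [], ec=ec)


@dataclass
class MetabolicModel:
    reactions: list[Reaction]
    biomass_id: str

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ModelError(f"duplicate reaction ids: {sorted(dup)}")
        if self.biomass_id not in ids:
            raise ModelError(f"biomass reaction {self.biomass_id!r} not in model")

    @property
    def metabolites(self) -> list[str]:
        mets: set[str] = set()
        for r in self.reactions:
            mets.update(r.stoichiometry)
        return sorted(mets)

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mets = self.metabolites
        met_idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[met_idx[m], j] = c
        return S, mets, [r.id for r in self.reactions]

    def without(self, reaction_ids: set[str]) -> "MetabolicModel":
        if self.biomass_id in reaction_ids:
            raise ModelError("cannot remove the biomass reaction")
        return MetabolicModel(
            [r for r in self.reactions if r.id not in reaction_ids], self.biomass_id)


def read_model(path: str | Path, biomass_id: str) -> MetabolicModel:
    """Read a reaction table (columns: id, formula, ec, genes ';'-separated)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"id", "formula"}
    if not needed <= set(table.columns):
        raise ModelError(f"{path}: reaction table needs columns {sorted(needed)}")
    reactions = []
    for row in table.itertuples():
        genes = [g.strip() for g in getattr(row, "genes", "").split(";") if g.strip()]
        reactions.append(make_reaction(row.id, row.formula,
                                       ec=getattr(row, "ec", ""), genes=genes))
    return MetabolicModel(reactions, biomass_id)


def remove_reactions_for_absent_genes(
        model: MetabolicModel, absent_genes: set[str]) -> tuple[MetabolicModel, list[str]]:
    """Drop reactions whose (non-empty) gene list is entirely absent.

    A reaction survives if any one of its genes is still present — an
    isozyme can carry the flux — and gene-less (spontaneous or
    unannotated) reactions are never removed. Returns the reduced model
    and the removed reaction ids.
    """
    removed = [r.id for r in model.reactions
               if r.genes and all(g in absent_genes for g in r.genes)]
    return model.without(set(removed)), removed


@dataclass
class Medium:
    """Uptake limits per exchange reaction (max inflow, >= 0).

    Exchanges listed here may import their metabolite up to the given
    rate; all other exchanges are export-only.
    """
    uptake: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.uptake.items() if v < 0}
        if bad:
            raise ModelError(f"negative uptake bounds: {bad}")


@dataclass
class FbaResult:
    objective: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.objective > GROWTH_THRESHOLD


def maximize_biomass(model: MetabolicModel, medium: Medium) -> FbaResult:
    """Maximal biomass flux: max v_biomass s.t. S.v = 0 and flux bounds.

    Exchange convention: positive exchange flux exports the metabolite;
    uptake is negative flux, so a medium entry u sets the exchange lower
    bound to -u. Exchanges not in the medium get lower bound 0.
    Objectives below 1e-9 are reported as exactly 0.
    """
    unknown = set(medium.uptake) - set(model.exchanges)
    if unknown:
        raise ModelError(f"medium names non-exchange reactions: {sorted(unknown)}")
    S, _mets, rids = model.stoichiometric_matrix()
    bounds = []
    for r in model.reactions:
        lo, hi = r.lower, r.upper
        if r.is_exchange:
            lo = -medium.uptake.get(r.id, 0.0)
            hi = DEFAULT_BOUND
        bounds.append((lo, hi))
    c = np.zeros(len(rids))
    c[rids.index(model.biomass_id)] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if not res.success:
        return FbaResult(0.0, {}, "infeasible")
    obj = float(-res.fun)
    if obj < ZERO_GROWTH_TOL:
        obj = 0.0
    return FbaResult(obj, dict(zip(rids, res.x.tolist())), "optimal")


def growth_phenotype_screen(model: MetabolicModel,
                            media: dict[str, Medium],
                            deletion_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Grow / no-grow matrix over (gene deletion set) x (medium).

    Each cell is True when the reduced model's maximal biomass flux
    exceeds 1e-6 on that medium.
    """
    rows = {}
    for del_name, absent in deletion_sets.items():
        reduced, _ = remove_reactions_for_absent_genes(model, absent)
        rows[del_name] = {med_name: maximize_biomass(reduced, med).grows
                          for med_name, med in media.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def write_result(result: FbaResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"objective": result.objective, "status": result.status,
                   "fluxes": result.fluxes}, fh, indent=1)
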