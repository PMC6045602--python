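"""Binding free-energy aggregation and resistance profiling.

End-state (MM/QM-GBSA style) energy terms are summed into free energies
G = E_vdw + E_ele + E_int + G_gb + G_surf (+ G_qm for mixed quantum/classical
schemes) − TΔS, combined into binding energies ΔG = G_complex − (G_receptor +
G_ligand), and differenced into per-(ligand, variant) mutation energies
ΔΔG_FR = ΔG_mt − ΔG_wt (positive = affinity lost on mutation). Predicted
mutation energies are validated against Ki-derived experimental values
RT·ln(Ki_mut/Ki_wt), and resistance is called with an ATP-competition rule:
a large affinity loss is resistant outright; a moderate one is resistant only
if the variant does not lose even more affinity for ATP, the inhibitor's
natural competitor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stability import MutationKey, parse_mutation_notation

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnergyDecomposition",
    "BindingRecord",
    "KiMeasurement",
    "SchemeEvaluation",
    "ResistanceCall",
    "total_free_energy",
    "g_surf_from_sasa",
    "binding_delta_g",
    "ddg_fr_predicted",
    "ddg_fr_experimental",
    "evaluate_scheme",
    "build_profile",
    "classify_resistance",
    "read_energy_table",
    "read_ki_table",
    "binding_records_from_table",
    "WILD_TYPE",
]

#: Gas constant, kcal K^-1 mol^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

WILD_TYPE = "wild_type"

QM_SCHEMES = {"AM1", "RM1", "PM6"}
SCHEMES = {"MM-GBSA", "MM-PBSA"} | QM_SCHEMES


@dataclass(frozen=True)
class EnergyDecomposition:
    e_vdw: float
    e_ele: float
    e_int: float
    g_gb: float
    g_surf: float
    g_qm: float | None = None
    minus_t_s: float = 0.0
    temperature: float = 300.0


@dataclass(frozen=True)
class BindingRecord:
    ligand: str
    variant: str  # mutation notation or WILD_TYPE
    scheme: str
    delta_g: float
    terms: EnergyDecomposition | None = None

    @property
    def mutation(self) -> MutationKey | None:
        return None if self.variant == WILD_TYPE else parse_mutation_notation(self.variant)


@dataclass(frozen=True)
class KiMeasurement:
    ligand: str
    variant: str
    ki_mutant: float
    ki_wildtype: float
    temperature: float = 300.0


@dataclass
class SchemeEvaluation:
    scheme: str
    pairs: list[tuple[float, float]]  # (predicted, experimental)
    r_squared: float


@dataclass(frozen=True)
class ResistanceCall:
    ligand: str
    variant: str
    ddg_fr_inhibitor: float
    ddg_fr_atp: float | None
    call: str
    rule_fired: str


def total_free_energy(terms: EnergyDecomposition) -> float:
    """G = H − TS with H = E_vdw + E_ele + E_int + G_gb + G_surf (+ G_qm).

    The entropy contribution enters as the pre-computed −TΔS column; when it
    is absent (0.0 default) only the enthalpic terms are summed.
    """
    required = ("e_vdw", "e_ele", "e_int", "g_gb", "g_surf")
    for name in required:
        v = getattr(terms, name)
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing or non-finite energy term: {name}")
    g = terms.e_vdw + terms.e_ele + terms.e_int + terms.g_gb + terms.g_surf + terms.minus_t_s
    if terms.g_qm is not None:
        if not math.isfinite(terms.g_qm):
            raise ValueError("missing or non-finite energy term: g_qm")
        g += terms.g_qm
    return g


def g_surf_from_sasa(sasa: float, gamma: float = 0.0072, beta: float = 0.0) -> float:
    """Nonpolar solvation term γ·SASA + β (kcal/mol; SASA in Å²)."""
    if sasa < 0:
        raise ValueError("SASA cannot be negative")
    return gamma * sasa + beta


def binding_delta_g(g_complex: float, g_receptor: float, g_ligand: float) -> float:
    """ΔG_bind = G_complex − (G_receptor + G_ligand)."""
    return g_complex - (g_receptor + g_ligand)


def ddg_fr_predicted(mutant: BindingRecord, wild_type: BindingRecord) -> float:
    """Mutation energy ΔΔG_FR = ΔG_mt − ΔG_wt; positive = affinity lost."""
    if mutant.ligand != wild_type.ligand:
        raise ValueError(f"ligand mismatch: {mutant.ligand} vs {wild_type.ligand}")
    if mutant.scheme != wild_type.scheme:
        raise ValueError(f"scheme mismatch: {mutant.scheme} vs {wild_type.scheme}")
    return mutant.delta_g - wild_type.delta_g


def ddg_fr_experimental(ki: KiMeasurement) -> float:
    """Experimental mutation energy RT·ln(Ki_mut / Ki_wt), kcal/mol."""
    if ki.ki_mutant <= 0 or ki.ki_wildtype <= 0:
        raise ValueError("Ki values must be positive")
    return GAS_CONSTANT_KCAL * ki.temperature * math.log(ki.ki_mutant / ki.ki_wildtype)


def evaluate_scheme(
    pairs: Sequence[tuple[float, float]], scheme: str = "", regression_r2: bool = False
) -> SchemeEvaluation:
    """Coefficient of determination between predicted and experimental ΔΔG_FR.

    Default is the squared Pearson correlation (identical to least-squares R²
    for a simple regression with intercept); ``regression_r2`` computes the
    regression form explicitly.
    """
    pairs = [(float(p), float(e)) for p, e in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (predicted, experimental) pairs")
    pred = np.array([p for p, _ in pairs])
    exp = np.array([e for _, e in pairs])
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise ValueError("constant vector: correlation undefined")
    if regression_r2:
        slope, intercept = np.polyfit(pred, exp, 1)
        resid = exp - (slope * pred + intercept)
        r2 = 1.0 - float((resid**2).sum()) / float(((exp - exp.mean()) ** 2).sum())
    else:
        r2 = float(stats.pearsonr(pred, exp).statistic ** 2)
    return SchemeEvaluation(scheme=scheme, pairs=pairs, r_squared=r2)


def build_profile(records: Sequence[BindingRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ligand × variant matrix of ΔΔG_FR plus per-ligand ΔG/ΔΔG summaries.

    ``records`` holds mutant rows and one wild-type row per ligand (same
    scheme). Missing (ligand, variant) cells stay NaN. Returns the matrix
    (ligands as rows) and a per-ligand summary table with extreme variants.
    """
    wt = {r.ligand: r for r in records if r.variant == WILD_TYPE}
    mutants = [r for r in records if r.variant != WILD_TYPE]
    missing = sorted({r.ligand for r in mutants} - set(wt))
    if missing:
        raise ValueError(f"ligand(s) lacking a wild-type reference: {missing}")
    rows = []
    for r in mutants:
        rows.append(
            {
                "ligand": r.ligand,
                "variant": r.variant,
                "delta_g_mt": r.delta_g,
                "ddg_fr": ddg_fr_predicted(r, wt[r.ligand]),
            }
        )
    long = pd.DataFrame(rows)
    matrix = long.pivot_table(index="ligand", columns="variant", values="ddg_fr")
    summaries = []
    for ligand, grp in long.groupby("ligand"):
        ddg = grp.set_index("variant")["ddg_fr"]
        dg = grp.set_index("variant")["delta_g_mt"]
        summaries.append(
            {
                "ligand": ligand,
                "n_variants": len(grp),
                "delta_g_wt": wt[ligand].delta_g,
                "mean_delta_g_mt": dg.mean(),
                "median_delta_g_mt": dg.median(),
                "min_delta_g_mt": dg.min(),
                "max_delta_g_mt": dg.max(),
                "mean_ddg_fr": ddg.mean(),
                "median_ddg_fr": ddg.median(),
                "min_ddg_fr": ddg.min(),
                "min_ddg_fr_variant": ddg.idxmin(),
                "max_ddg_fr": ddg.max(),
                "max_ddg_fr_variant": ddg.idxmax(),
            }
        )
    return matrix, pd.DataFrame(summaries).set_index("ligand")


def classify_resistance(
    ddg_fr_inhibitor: float,
    ddg_fr_atp: float | None = None,
    high_threshold: float = 8.0,
    ligand: str = "",
    variant: str = "",
) -> ResistanceCall:
    """ATP-competition resistance call.

    Rule order: (1) inhibitor affinity loss at or above ``high_threshold``
    kcal/mol → resistant outright; (2) otherwise, if the variant loses even
    more affinity for ATP than for the inhibitor → likely_sensitive (the
    inhibitor still out-competes ATP); (3) otherwise (ties included, the
    conservative reading) → resistant; (4) no ATP value and below threshold →
    indeterminate.
    """
    if not math.isfinite(ddg_fr_inhibitor):
        raise ValueError("ddg_fr_inhibitor must be finite")
    if ddg_fr_inhibitor >= high_threshold:
        call, rule = "resistant", "high_affinity_loss"
    elif ddg_fr_atp is None:
        call, rule = "indeterminate", "no_atp_reference"
    elif ddg_fr_inhibitor < ddg_fr_atp:
        call, rule = "likely_sensitive", "atp_loses_more"
    else:
        call, rule = "resistant", "atp_competitive"
    return ResistanceCall(
        ligand=ligand,
        variant=variant,
        ddg_fr_inhibitor=ddg_fr_inhibitor,
        ddg_fr_atp=ddg_fr_atp,
        call=call,
        rule_fired=rule,
    )


ENERGY_COLUMNS = [
    "ligand",
    "variant",
    "scheme",
    "role",
    "e_vdw",
    "e_ele",
    "e_int",
    "g_gb",
    "g_surf",
    "g_qm",
    "minus_t_s",
    "delta_g",
]


def read_energy_table(path_or_buffer) -> pd.DataFrame:
    df = pd.read_csv(path_or_buffer, sep="\t")
    needed = {"ligand", "variant", "scheme", "role"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    return df


def binding_records_from_table(df: pd.DataFrame) -> list[BindingRecord]:
    """Build binding records from an energy table.

    Rows with ``role == 'binding'`` carry ΔG directly in ``delta_g``;
    otherwise complex/receptor/ligand triplets are summed term-wise via
    :func:`total_free_energy` and combined. A missing −TΔS column is treated
    as zero (with a warning), matching enthalpy-only end-state practice.
    """
    if "minus_t_s" not in df.columns:
        warnings.warn("no minus_t_s column: entropy term treated as 0", stacklevel=2)
        df = df.assign(minus_t_s=0.0)
    records: list[BindingRecord] = []
    direct = df[df["role"] == "binding"]
    for _, row in direct.iterrows():
        records.append(
            BindingRecord(
                ligand=row["ligand"],
                variant=row["variant"],
                scheme=row["scheme"],
                delta_g=float(row["delta_g"]),
            )
        )
    parts = df[df["role"].isin(["complex", "receptor", "ligand"])]
    for (ligand, variant, scheme), grp in parts.groupby(["ligand", "variant", "scheme"]):
        roles = dict(zip(grp["role"], grp.index))
        if set(roles) != {"complex", "receptor", "ligand"}:
            raise ValueError(f"incomplete complex/receptor/ligand triplet for ({ligand}, {variant}, {scheme})")
        g = {}
        for role, idx in roles.items():
            row = df.loc[idx]
            qm = float(row["g_qm"]) if "g_qm" in df.columns and np.isfinite(row.get("g_qm", np.nan)) else None
            if scheme in QM_SCHEMES and qm is None:
                raise ValueError(f"QM scheme {scheme} requires a g_qm term ({role} row)")
            terms = EnergyDecomposition(
                e_vdw=float(row["e_vdw"]),
                e_ele=float(row["e_ele"]),
                e_int=float(row["e_int"]),
                g_gb=float(row["g_gb"]),
                g_surf=float(row["g_surf"]),
                g_qm=qm,
                minus_t_s=float(row["minus_t_s"]),
            )
            g[role] = total_free_energy(terms)
        records.append(
            BindingRecord(
                ligand=ligand,
                variant=variant,
                scheme=scheme,
                delta_g=binding_delta_g(g["complex"], g["receptor"], g["ligand"]),
            )
        )
    if not records:
        raise ValueError("no binding records in table")
    return records


def read_ki_table(path_or_buffer) -> list[KiMeasurement]:
    df = pd.read_csv(path_or_buffer, sep="\t")
    needed = {"ligand", "variant", "ki_mut", "ki_wt"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"Ki table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            KiMeasurement(
                ligand=row["ligand"],
                variant=row["variant"],
                ki_mutant=float(row["ki_mut"]),
                ki_wildtype=float(row["ki_wt"]),
                temperature=float(row["temperature"]) if "temperature" in df.columns else 300.0,
            )
        )
    return out
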