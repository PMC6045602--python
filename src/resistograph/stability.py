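"""Folding-stability (ΔΔG_fold) landscape analysis.

Per-mutation stability changes (mutant minus wild type, kcal/mol, positive =
destabilizing) are ingested as replicate tables, averaged, binned into seven
categories at ±0.46/±0.92/±1.84 kcal/mol, summarized as landscape counts,
kernel-smoothed into density curves, and correlated with per-residue solvent
exposure via Spearman's rank correlation.

The bin half-widths are multiples of 0.46 kcal/mol, the reported accuracy of
the empirical force field that produces such tables, so "neutral" means
indistinguishable from zero at that accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structio import ResidueSASA

__all__ = [
    "AMINO_ACIDS",
    "CATEGORY_BOUNDS",
    "STABILITY_CATEGORIES",
    "MutationKey",
    "StabilityRecord",
    "DensityCurve",
    "parse_mutation_notation",
    "average_replicates",
    "classify_stability",
    "landscape_summary",
    "kde_density",
    "find_peaks",
    "spearman_rho",
    "correlate_sasa_stability",
    "read_stability_table",
    "load_resistance_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Symmetric bin edges (kcal/mol); 0.46 is the stability-predictor accuracy.
CATEGORY_BOUNDS = (0.46, 0.92, 1.84)

STABILITY_CATEGORIES = (
    "highly_stabilizing",
    "stabilizing",
    "slightly_stabilizing",
    "neutral",
    "slightly_destabilizing",
    "destabilizing",
    "highly_destabilizing",
)

_SITE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MutationKey:
    """One or more point substitutions, e.g. L1196M or E1210K/S1206C."""

    sites: tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        if not self.sites:
            raise ValueError("a mutation needs at least one site")

    @property
    def notation(self) -> str:
        return "/".join(f"{wt}{pos}{mut}" for wt, pos, mut in self.sites)

    @property
    def is_multi_site(self) -> bool:
        return len(self.sites) > 1

    @property
    def is_synonymous(self) -> bool:
        return all(wt == mut for wt, _, mut in self.sites)

    def __str__(self) -> str:
        return self.notation


@dataclass
class StabilityRecord:
    mutation: MutationKey
    replicate_ddg: list[float] = field(default_factory=list)
    ddg_fold: float = float("nan")
    std: float = 0.0
    category: str = ""
    provenance: str = "all_possible"

    @classmethod
    def from_replicates(
        cls, mutation: MutationKey, replicate_ddg: Sequence[float], provenance: str = "all_possible", ddof: int = 1
    ) -> "StabilityRecord":
        mean, std = average_replicates(replicate_ddg, ddof=ddof)
        return cls(
            mutation=mutation,
            replicate_ddg=list(replicate_ddg),
            ddg_fold=mean,
            std=std,
            category=classify_stability(mean),
            provenance=provenance,
        )


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def parse_mutation_notation(text: str) -> MutationKey:
    """Parse 'L1196M' or slash-joined multi-site notation into a key."""
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty mutation notation")
    sites = []
    for part in text.strip().split("/"):
        m = _SITE_RE.match(part.strip())
        if m is None:
            raise ValueError(f"malformed mutation notation: {part!r}")
        wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
            raise ValueError(f"not an amino-acid letter in {part!r}")
        if pos <= 0:
            raise ValueError(f"non-positive residue number in {part!r}")
        sites.append((wt, pos, mut))
    return MutationKey(sites=tuple(sites))


def average_replicates(replicate_ddg: Sequence[float], ddof: int = 1) -> tuple[float, float]:
    """Mean and standard deviation of replicate ΔΔG values.

    ``ddof=1`` (sample std) by default; a single replicate has std 0.
    """
    values = np.asarray(list(replicate_ddg), dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite replicate value")
    mean = float(values.mean())
    std = 0.0 if values.size <= ddof else float(values.std(ddof=ddof))
    return mean, std


def classify_stability(ddg_fold: float) -> str:
    """Seven-category stability bin for a ΔΔG_fold value (kcal/mol).

    Intervals are closed toward zero:
    (−∞,−1.84) / [−1.84,−0.92) / [−0.92,−0.46) / [−0.46,0.46] /
    (0.46,0.92] / (0.92,1.84] / (1.84,∞).
    """
    x = float(ddg_fold)
    if not np.isfinite(x):
        raise ValueError("ΔΔG_fold must be finite")
    b1, b2, b3 = CATEGORY_BOUNDS
    if x < -b3:
        return "highly_stabilizing"
    if x < -b2:
        return "stabilizing"
    if x < -b1:
        return "slightly_stabilizing"
    if x <= b1:
        return "neutral"
    if x <= b2:
        return "slightly_destabilizing"
    if x <= b3:
        return "destabilizing"
    return "highly_destabilizing"


def landscape_summary(records: Sequence[StabilityRecord]) -> dict:
    """Counts and fractions per category plus the moderate/extreme bands."""
    if not records:
        raise ValueError("no stability records")
    values = np.array([r.ddg_fold for r in records], dtype=float)
    cats = [r.category or classify_stability(r.ddg_fold) for r in records]
    n = len(records)
    per_category = {c: cats.count(c) for c in STABILITY_CATEGORIES}
    b3 = CATEGORY_BOUNDS[2]
    n_high_destab = per_category["highly_destabilizing"]
    n_high_stab = per_category["highly_stabilizing"]
    summary = {
        "n_total": n,
        "n_moderate": n - n_high_destab - n_high_stab,
        "n_highly_destabilizing": n_high_destab,
        "n_highly_stabilizing": n_high_stab,
        "n_stabilizing_any": int((values < 0).sum()),
        "per_category": per_category,
        "fractions": {c: per_category[c] / n for c in STABILITY_CATEGORIES},
        "fraction_moderate": (n - n_high_destab - n_high_stab) / n,
        "mean": float(values.mean()),
        "median": float(np.median(values)),
    }
    return summary


def silverman_bandwidth(values: np.ndarray) -> float:
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * a * values.size ** (-0.2)


def kde_density(values: Sequence[float], bandwidth: float | None = None, grid_points: int = 512) -> DensityCurve:
    """Gaussian kernel density estimate over an extended grid.

    Bandwidth defaults to Silverman's rule of thumb; the grid spans
    [min−3h, max+3h] so the curve integrates to 1 within truncation error.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.ptp(v) == 0:
        raise ValueError("constant input has zero bandwidth")
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(v)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    # 4 bandwidths of margin keep the truncated kernel mass below 1e-4,
    # so the trapezoidal integral stays within 1e-3 of unity
    grid = np.linspace(v.min() - 4 * h, v.max() + 4 * h, max(grid_points, 512))
    z = (grid[:, None] - v[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=h)


def find_peaks(curve: DensityCurve, min_prominence: float = 0.0) -> list[tuple[float, float]]:
    """Local maxima of a density curve, highest density first.

    With the default ``min_prominence=0`` every strict sign change of the
    first difference counts. A positive value (fraction of the maximum
    density) suppresses sampling ripples and far-tail blips, keeping only
    modes whose dip to the surrounding curve is at least that deep.
    """
    d = curve.density
    if min_prominence > 0.0:
        from scipy.signal import find_peaks as _sp_find_peaks

        idx = _sp_find_peaks(d, prominence=min_prominence * d.max())[0].tolist()
    else:
        # first-difference sign change; a flat plateau between an ascent and
        # a descent counts once, at its midpoint
        diffs = np.diff(d)
        idx = []
        ascent_top = None
        for i, di in enumerate(diffs):
            if di > 0:
                ascent_top = i + 1
            elif di < 0:
                if ascent_top is not None:
                    idx.append((ascent_top + i) // 2)
                    ascent_top = None
    peaks = [(float(curve.grid[i]), float(d[i])) for i in idx]
    return sorted(peaks, key=lambda p: -p[1])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks for ties)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined rank correlation")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_sasa_stability(
    records: Sequence[StabilityRecord], sasa: Sequence[ResidueSASA]
) -> tuple[float, pd.DataFrame]:
    """Pair single-site mutations with their residue's SASA and correlate.

    Multi-site mutations have no single residue exposure and are excluded.
    Returns Spearman's rho and the paired table for export.
    """
    by_residue = {r.residue_number: r.sasa for r in sasa}
    rows = []
    missing = []
    for rec in records:
        if rec.mutation.is_multi_site:
            continue
        _, pos, _ = rec.mutation.sites[0]
        if pos not in by_residue:
            missing.append(pos)
            continue
        rows.append((rec.mutation.notation, pos, rec.ddg_fold, by_residue[pos]))
    if missing:
        raise KeyError(f"residues absent from SASA table: {sorted(set(missing))}")
    if len(rows) < 3:
        raise ValueError("need at least 3 single-site mutations with SASA")
    table = pd.DataFrame(rows, columns=["mutation", "residue_number", "ddg_fold", "sasa"])
    rho = spearman_rho(table["ddg_fold"], table["sasa"])
    return rho, table


def read_stability_table(path_or_buffer, provenance: str | None = None, ddof: int = 1) -> list[StabilityRecord]:
    """Read a TSV/CSV with columns ``mutation, ddg_run1..K`` or ``mutation, ddg_fold[, sd]``."""
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    if "mutation" not in df.columns:
        raise ValueError("table must have a 'mutation' column")
    run_cols = [c for c in df.columns if re.fullmatch(r"ddg_run\d+", c)]
    records = []
    for _, row in df.iterrows():
        key = parse_mutation_notation(str(row["mutation"]))
        prov = provenance or str(row.get("provenance", "all_possible"))
        if run_cols:
            reps = [float(row[c]) for c in run_cols if np.isfinite(row[c])]
            records.append(StabilityRecord.from_replicates(key, reps, provenance=prov, ddof=ddof))
        elif "ddg_fold" in df.columns:
            ddg = float(row["ddg_fold"])
            records.append(
                StabilityRecord(
                    mutation=key,
                    ddg_fold=ddg,
                    std=float(row["sd"]) if "sd" in df.columns and np.isfinite(row.get("sd", np.nan)) else 0.0,
                    category=classify_stability(ddg),
                    provenance=prov,
                )
            )
        else:
            raise ValueError("table needs ddg_run* columns or a ddg_fold column")
    if not records:
        raise ValueError("empty stability table")
    return records


def load_resistance_table() -> pd.DataFrame:
    """The bundled table of reported ALK resistance mutations.

    Columns: mutation, ddg_fold (kcal/mol), sd, delta_e (epistatic mutation
    effect score), provenance (primary vs secondary resistance).
    """
    with resources.files("resistograph.data").joinpath("alk_resistance_mutations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
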