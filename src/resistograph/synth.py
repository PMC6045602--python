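"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without external downloads: toy
poly-alanine structures, stability landscapes whose observed subset is a
two-component mixture with a destabilizing peak (default centre 3.12
kcal/mol) against a unimodal near-zero all-possible background, a planted
rank correlation between per-residue solvent exposure and ΔΔG_fold (Gaussian
copula, so the target Spearman rho is known analytically), random Potts
models, binding-energy/Ki tables with known resistant/sensitive ground
truth, and trajectories built from a reference structure plus orthonormal
planted collective modes plus thermal noise.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binding import GAS_CONSTANT_KCAL, WILD_TYPE, BindingRecord, KiMeasurement
from .evo import PottsModel
from .stability import AMINO_ACIDS
from .structio import AtomRecord, Structure
from .trajectory import Trajectory

__all__ = [
    "LandscapeConfig",
    "EnergyTableConfig",
    "TrajectoryConfig",
    "GeneratorConfig",
    "gen_toy_structure",
    "gen_stability_landscape",
    "gen_potts_model",
    "gen_energy_tables",
    "gen_trajectory",
]


@dataclass
class LandscapeConfig:
    """Stability-landscape generator settings.

    The observed mixture defaults echo a clinical mutation set: a small
    near-neutral component and a destabilizing component centred at 3.12
    kcal/mol. The SASA association is planted through a Gaussian copula with
    a target Spearman rho (default −0.57) over non-synonymous mutations.
    """

    n_positions: int = 247
    residue_offset: int = 1116  # author numbering of the first position
    n_observed: int = 145
    observed_weights: tuple[float, ...] = (0.45, 0.55)
    observed_means: tuple[float, ...] = (0.3, 3.12)
    observed_sds: tuple[float, ...] = (0.6, 1.2)
    all_possible_mean: float = 0.2
    all_possible_sd: float = 1.0
    spearman_target: float = -0.57
    sasa_scale: float = 40.0  # exponential marginal scale, Å²
    replicate_sd: float = 0.05
    n_replicates: int = 3

    def validate(self) -> None:
        if abs(sum(self.observed_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s < 0 for s in self.observed_sds) or self.all_possible_sd < 0 or self.replicate_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.spearman_target < 1.0:
            raise ValueError("spearman_target must lie in (−1, 1)")


@dataclass
class EnergyTableConfig:
    ligands: tuple[str, ...] = ("crizotinib", "ceritinib", "alectinib", "lorlatinib")
    atp_ligand: str = "ATP"
    n_variants: int = 10
    resistant_fraction: float = 0.5
    wild_type_dg_mean: float = -40.0
    wild_type_dg_sd: float = 5.0
    atp_wild_type_dg: float = -18.0
    resistance_effect: float = 10.0  # ΔΔG_FR planted on resistant cells, kcal/mol
    sensitive_effect: float = 0.5
    atp_margin: float = 3.0  # ATP ΔΔG_FR for sensitive variants sits above this
    noise_sd: float = 0.0
    ki_noise_sd: float = 0.0  # lognormal sigma on Ki ratios
    ki_wildtype_nM: float = 5.0
    scheme: str = "AM1"
    temperature: float = 300.0

    def validate(self) -> None:
        if self.resistance_effect <= 0:
            raise ValueError("resistance effect size must be positive")
        if self.noise_sd < 0 or self.ki_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError("resistant_fraction must be in [0, 1]")


@dataclass
class TrajectoryConfig:
    n_frames: int = 2000
    dt_ps: float = 1.0
    thermal_sd: float = 0.05  # Å per coordinate; small vs mode amplitudes so
    # the planted collective modes dominate the covariance spectrum
    amplitudes: tuple[float, ...] = (3.0, 1.0)
    frequencies: tuple[float, ...] | None = None  # rad/ps; auto-spaced if None
    rigid_motion: bool = False

    def validate(self) -> None:
        if self.thermal_sd < 0:
            raise ValueError("thermal_sd must be non-negative")
        if self.thermal_sd == 0 and not self.amplitudes:
            raise ValueError("need at least one planted mode or thermal noise")


@dataclass
class GeneratorConfig:
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    energies: EnergyTableConfig = field(default_factory=EnergyTableConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    potts_L: int = 6
    potts_q: int = 4
    potts_density: float = 0.5


def gen_toy_structure(n_res: int, geometry: str = "ideal_helix") -> Structure:
    """Deterministic poly-alanine backbone trace (N, CA, C, O, CB per residue).

    ``ideal_helix`` places Cα on a 2.3 Å-radius helix with 1.5 Å rise and
    100° twist per residue (Cα–Cα ≈ 3.8 Å); ``extended`` is a flat zigzag
    with 3.8 Å Cα spacing.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    if geometry not in ("ideal_helix", "extended"):
        raise ValueError("geometry must be 'ideal_helix' or 'extended'")
    ca = np.empty((n_res, 3))
    if geometry == "ideal_helix":
        for i in range(n_res):
            theta = math.radians(100.0) * i
            ca[i] = (2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i)
    else:
        for i in range(n_res):
            ca[i] = (0.9 * (-1) ** i, 0.0, 3.6932 * i)
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_res):
        tangent = ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        up = np.array([0.0, 0.0, 1.0])
        normal = np.cross(tangent, up)
        if np.linalg.norm(normal) < 1e-6:
            normal = np.array([1.0, 0.0, 0.0])
        normal = normal / np.linalg.norm(normal)
        binormal = np.cross(tangent, normal)
        offsets = {
            "N": -1.2 * tangent + 0.3 * normal,
            "CA": np.zeros(3),
            "C": 1.2 * tangent + 0.3 * normal,
            "O": 1.4 * tangent + 1.3 * normal,
            "CB": 1.3 * binormal - 0.5 * normal,
        }
        for name, off in offsets.items():
            x, y, z = ca[i] + off
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    chain_id="A",
                    residue_number=i + 1,
                    insertion_code="",
                    position=(float(x), float(y), float(z)),
                )
            )
            serial += 1
    return Structure(atoms=atoms, identifier=f"toy_{geometry}_{n_res}")


def _mixture_ppf(u: np.ndarray, weights, means, sds) -> np.ndarray:
    """Numeric inverse CDF of a Gaussian mixture (monotone interpolation)."""
    lo = min(m - 6 * s for m, s in zip(means, sds))
    hi = max(m + 6 * s for m, s in zip(means, sds))
    grid = np.linspace(lo, hi, 4096)
    cdf = np.zeros_like(grid)
    for w, m, s in zip(weights, means, sds):
        cdf += w * stats.norm.cdf(grid, loc=m, scale=s)
    return np.interp(u, cdf, grid)


def gen_stability_landscape(
    config: LandscapeConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(all_possible, observed, sasa) tables for the stability stage.

    ``all_possible`` holds 20 rows per position (the synonymous self-mutation
    carries ΔΔG exactly 0); non-synonymous ΔΔG values are tied to per-residue
    SASA through a Gaussian copula so their Spearman rho targets
    ``config.spearman_target``. ``observed`` draws from the bimodal mixture.
    Replicate columns average exactly to the planted ΔΔG.
    """
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_pos = config.n_positions
    offset = config.residue_offset

    # Gaussian copula: latent residue variable drives SASA, correlated latent
    # drives ΔΔG; Spearman(rho_s) maps to latent Pearson r = 2 sin(pi*rho_s/6).
    r_latent = 2.0 * math.sin(math.pi * config.spearman_target / 6.0)
    z_res = rng.standard_normal(n_pos)
    sasa_vals = -config.sasa_scale * np.log1p(-stats.norm.cdf(z_res))  # exponential marginal

    wt_letters = rng.choice(list(AMINO_ACIDS), size=n_pos)
    rows = []
    for p in range(n_pos):
        resnum = offset + p
        wt = wt_letters[p]
        for mut in AMINO_ACIDS:
            if mut == wt:
                ddg = 0.0
            else:
                z = r_latent * z_res[p] + math.sqrt(1 - r_latent**2) * rng.standard_normal()
                ddg = config.all_possible_mean + config.all_possible_sd * z
            rows.append((f"{wt}{resnum}{mut}", ddg))
    all_df = _with_replicates(pd.DataFrame(rows, columns=["mutation", "ddg"]), config, rng)
    all_df["provenance"] = "all_possible"

    # observed subset: bimodal mixture, sampled at random positions
    obs_rows = []
    seen = set()
    u = rng.uniform(size=config.n_observed)
    ddg_obs = _mixture_ppf(u, config.observed_weights, config.observed_means, config.observed_sds)
    k = 0
    while len(obs_rows) < config.n_observed:
        p = int(rng.integers(n_pos))
        wt = wt_letters[p]
        mut = rng.choice([a for a in AMINO_ACIDS if a != wt])
        key = (p, mut)
        if key in seen:
            continue
        seen.add(key)
        obs_rows.append((f"{wt}{offset + p}{mut}", float(ddg_obs[k])))
        k += 1
    obs_df = _with_replicates(pd.DataFrame(obs_rows, columns=["mutation", "ddg"]), config, rng)
    obs_df["provenance"] = "observed"

    sasa_df = pd.DataFrame(
        {
            "chain": "A",
            "resnum": np.arange(offset, offset + n_pos),
            "resname": "ALA",
            "sasa_A2": sasa_vals,
            "exposure": [
                "buried" if s < 5 else ("exposed" if s > 70 else "intermediate") for s in sasa_vals
            ],
        }
    )
    return all_df, obs_df, sasa_df


def _with_replicates(df: pd.DataFrame, config: LandscapeConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, k = len(df), config.n_replicates
    noise = rng.normal(scale=config.replicate_sd, size=(n, k)) if config.replicate_sd > 0 else np.zeros((n, k))
    noise -= noise.mean(axis=1, keepdims=True)  # replicates average exactly to the planted value
    out = pd.DataFrame({"mutation": df["mutation"]})
    for j in range(k):
        out[f"ddg_run{j + 1}"] = df["ddg"].to_numpy() + noise[:, j]
    return out


def gen_potts_model(
    L: int, q: int, density: float = 0.5, seed: int = 0, field_sd: float = 1.0, coupling_sd: float = 0.5
) -> tuple[PottsModel, str]:
    """Random Potts model (normal fields, sparse normal couplings) plus a
    wild-type sequence drawn uniformly over the alphabet."""
    if L < 2 or q < 2:
        raise ValueError("need L >= 2 and q >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("coupling density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = AMINO_ACIDS[:q]
    h = rng.normal(scale=field_sd, size=(L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            if rng.uniform() < density:
                J[i, j] = rng.normal(scale=coupling_sd, size=(q, q))
    wt = "".join(rng.choice(list(alphabet), size=L))
    return PottsModel(alphabet=alphabet, h=h, J=J), wt


def gen_energy_tables(
    config: EnergyTableConfig | None = None, seed: int = 0
) -> tuple[list[BindingRecord], list[KiMeasurement], pd.DataFrame]:
    """Binding records, Ki measurements and the planted truth table.

    Resistant (ligand, variant) cells get ΔG_mt = ΔG_wt + resistance_effect,
    sensitive cells + sensitive_effect, each plus Gaussian noise; ATP rows are
    built so the ATP-competition rule discriminates (sensitive variants lose
    more affinity for ATP than for the inhibitor). Ki values invert the
    RT·ln formula from the planted ΔΔG (times lognormal noise), so at zero
    noise predicted and experimental mutation energies agree exactly.
    """
    config = config or EnergyTableConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    rt = GAS_CONSTANT_KCAL * config.temperature

    positions = 1151 + 5 * np.arange(config.n_variants)
    wt_letters = rng.choice(list(AMINO_ACIDS), size=config.n_variants)
    variants = []
    for p, wt in zip(positions, wt_letters):
        mut = rng.choice([a for a in AMINO_ACIDS if a != wt])
        variants.append(f"{wt}{p}{mut}")
    n_resistant = int(round(config.resistant_fraction * config.n_variants))
    resistant = np.zeros(config.n_variants, dtype=bool)
    resistant[rng.permutation(config.n_variants)[:n_resistant]] = True

    records: list[BindingRecord] = []
    kis: list[KiMeasurement] = []
    truth_rows = []
    noise = lambda: rng.normal(scale=config.noise_sd) if config.noise_sd > 0 else 0.0

    atp_wt_dg = config.atp_wild_type_dg
    records.append(BindingRecord(config.atp_ligand, WILD_TYPE, config.scheme, atp_wt_dg))
    atp_ddg = {}
    for v, is_res in zip(variants, resistant):
        # sensitive variants must lose strictly more affinity for ATP than for
        # the inhibitor; resistant ones are caught by the threshold branch
        planted = config.atp_margin + config.sensitive_effect if not is_res else config.sensitive_effect
        atp_ddg[v] = planted
        records.append(BindingRecord(config.atp_ligand, v, config.scheme, atp_wt_dg + planted + noise()))

    for ligand in config.ligands:
        dg_wt = config.wild_type_dg_mean + (
            rng.normal(scale=config.wild_type_dg_sd) if config.wild_type_dg_sd > 0 else 0.0
        )
        records.append(BindingRecord(ligand, WILD_TYPE, config.scheme, dg_wt))
        for v, is_res in zip(variants, resistant):
            planted = config.resistance_effect if is_res else config.sensitive_effect
            records.append(BindingRecord(ligand, v, config.scheme, dg_wt + planted + noise()))
            ki_wt = config.ki_wildtype_nM
            ratio = math.exp(planted / rt)
            if config.ki_noise_sd > 0:
                ratio *= math.exp(rng.normal(scale=config.ki_noise_sd))
            kis.append(KiMeasurement(ligand, v, ki_mutant=ki_wt * ratio, ki_wildtype=ki_wt))
            truth_rows.append(
                {
                    "ligand": ligand,
                    "variant": v,
                    "resistant": bool(is_res),
                    "planted_ddg_fr": planted,
                    "planted_ddg_fr_atp": atp_ddg[v],
                }
            )
    return records, kis, pd.DataFrame(truth_rows)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_trajectory(
    reference: Structure | np.ndarray,
    config: TrajectoryConfig | None = None,
    seed: int = 0,
    modes: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory = reference + planted sinusoidal collective modes + noise.

    Modes are orthonormal 3N vectors (random ones are drawn when not given;
    supplied non-orthonormal modes are Gram–Schmidt-corrected with a
    warning). Each mode m oscillates as amplitude_m·sin(ω_m t + φ_m), so its
    coordinate variance is amplitude²/2. With ``rigid_motion`` a random
    rigid roto-translation is applied per frame to exercise superposition
    removal. Returns the trajectory and the planted modes (k × 3N).
    """
    config = config or TrajectoryConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    ref = reference.coordinates if isinstance(reference, Structure) else np.asarray(reference, dtype=float)
    n_atoms = ref.shape[0]
    dim = 3 * n_atoms
    k = len(config.amplitudes)

    if modes is None:
        modes_m = np.linalg.qr(rng.standard_normal((dim, k)))[0].T if k else np.zeros((0, dim))
    else:
        modes_m = np.asarray(modes, dtype=float).reshape(k, dim)
        gram = modes_m @ modes_m.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            warnings.warn("planted modes not orthonormal; re-orthonormalizing", stacklevel=2)
            modes_m = np.linalg.qr(modes_m.T)[0].T

    times = np.arange(config.n_frames) * config.dt_ps
    freqs = (
        np.asarray(config.frequencies, dtype=float)
        if config.frequencies is not None
        else 0.37 + 0.36 * np.arange(k)
    )
    phases = rng.uniform(0, 2 * math.pi, size=k)
    coords = np.repeat(ref.reshape(1, dim), config.n_frames, axis=0)
    for m in range(k):
        coords += (
            config.amplitudes[m] * np.sin(freqs[m] * times + phases[m])[:, None] * modes_m[m][None, :]
        )
    if config.thermal_sd > 0:
        coords += rng.normal(scale=config.thermal_sd, size=coords.shape)
    coords = coords.reshape(config.n_frames, n_atoms, 3)
    if config.rigid_motion:
        # frame 0 stays put so superposing to it recovers the unmoved frames
        for f in range(1, config.n_frames):
            rot = _random_rotation(rng)
            shift = rng.normal(scale=5.0, size=3)
            coords[f] = coords[f] @ rot.T + shift
    labels = (
        [(a.chain_id, a.residue_number, a.name) for a in reference.atoms]
        if isinstance(reference, Structure)
        else []
    )
    return Trajectory(times=times, coords=coords, atom_labels=labels), modes_m
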