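"""Epistatic mutation-effect scoring under a pairwise (Potts) sequence model.

A Potts model assigns each sequence an energy from per-position fields h and
pairwise couplings J (defined for position pairs i<j). The mutation effect
score ΔE = E(mutant) − E(wild type) evaluates substitutions jointly, so
multi-site mutations pick up coupling (epistatic) contributions that an
additive model would miss. More negative ΔE reads as more damaging.

Model fitting is out of scope here: models are read from a plain-text
parameter file or generated synthetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stability import MutationKey

__all__ = ["PottsModel", "EvoScore", "sequence_energy", "delta_e", "summarize_scores", "read_potts_model", "write_potts_model"]


@dataclass
class PottsModel:
    """Fields h (L×q) and couplings J (L×L×q×q, populated for i<j only)."""

    alphabet: str
    h: np.ndarray
    J: np.ndarray
    position_map: dict[int, int] = field(default_factory=dict)  # model index (0-based) -> author residue number

    def __post_init__(self):
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J must have shape {(L, L, q, q)}, got {self.J.shape}")
        if len(self.alphabet) != q:
            raise ValueError("alphabet length must match field dimension")
        if not self.position_map:
            self.position_map = {i: i + 1 for i in range(L)}
        if len(set(self.position_map.values())) != len(self.position_map):
            raise ValueError("position_map must be injective")

    @property
    def length(self) -> int:
        return self.h.shape[0]

    def index_of_residue(self, residue_number: int) -> int:
        for idx, num in self.position_map.items():
            if num == residue_number:
                return idx
        raise KeyError(f"residue {residue_number} is not covered by the model")

    def encode(self, sequence: str) -> np.ndarray:
        if len(sequence) != self.length:
            raise ValueError(f"sequence length {len(sequence)} != model length {self.length}")
        try:
            return np.array([self.alphabet.index(c) for c in sequence.upper()])
        except ValueError:
            bad = sorted({c for c in sequence.upper() if c not in self.alphabet})
            raise ValueError(f"letters outside the model alphabet: {bad}") from None


@dataclass(frozen=True)
class EvoScore:
    mutation: MutationKey
    delta_e: float
    pathogenicity_label: str = "not_specified"


def sequence_energy(model: PottsModel, sequence: str) -> float:
    """E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j)."""
    s = model.encode(sequence)
    L = model.length
    e = float(model.h[np.arange(L), s].sum())
    iu, ju = np.triu_indices(L, k=1)
    e += float(model.J[iu, ju, s[iu], s[ju]].sum())
    return e


def _mutate(model: PottsModel, wt_sequence: str, mutation: MutationKey) -> str:
    seq = list(wt_sequence.upper())
    for wt, pos, mut in mutation.sites:
        idx = model.index_of_residue(pos)
        if seq[idx] != wt:
            raise ValueError(
                f"wild-type mismatch at residue {pos}: sequence has {seq[idx]}, mutation says {wt}"
            )
        seq[idx] = mut
    return "".join(seq)


def delta_e(model: PottsModel, wt_sequence: str, mutation: MutationKey, label: str = "not_specified") -> EvoScore:
    """ΔE = E(mutant) − E(wild type); multi-site mutations applied jointly."""
    wt = wt_sequence.upper()
    mutant = _mutate(model, wt, mutation)
    score = sequence_energy(model, mutant) - sequence_energy(model, wt)
    return EvoScore(mutation=mutation, delta_e=score, pathogenicity_label=label)


def summarize_scores(scores: Sequence[EvoScore], label: str | None = None) -> dict:
    """Order statistics of ΔE over an optional pathogenicity subset."""
    subset = [s for s in scores if label is None or s.pathogenicity_label == label]
    if not subset:
        raise ValueError("no scores after filtering")
    v = np.array([s.delta_e for s in subset], dtype=float)
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
    }


def write_potts_model(model: PottsModel, path) -> None:
    """Serialize to the plain-text parameter format (1-based positions)."""
    L, q = model.h.shape
    with open(path, "w") as fh:
        fh.write(f"ALPHABET {model.alphabet}\n")
        fh.write(f"L {L}\n")
        for i in range(L):
            fh.write(f"POS {i + 1} {model.position_map[i]}\n")
        for i in range(L):
            for a in range(q):
                if model.h[i, a] != 0.0:
                    fh.write(f"H {i + 1} {model.alphabet[a]} {float(model.h[i, a])!r}\n")
        for i in range(L):
            for j in range(i + 1, L):
                for a in range(q):
                    for b in range(q):
                        if model.J[i, j, a, b] != 0.0:
                            fh.write(
                                f"J {i + 1} {j + 1} {model.alphabet[a]} {model.alphabet[b]} "
                                f"{float(model.J[i, j, a, b])!r}\n"
                            )


def read_potts_model(path) -> PottsModel:
    """Read the plain-text parameter format written by :func:`write_potts_model`.

    Lines: ``ALPHABET <letters>``, ``L <int>``, optional ``POS i resnum``
    mappings, then ``H i letter value`` and ``J i j letter letter value``
    entries with 1-based model positions. '#' starts a comment.
    """
    alphabet = None
    L = None
    pos_map: dict[int, int] = {}
    h_entries: list[tuple[int, str, float]] = []
    j_entries: list[tuple[int, int, str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                if tok[0] == "ALPHABET":
                    alphabet = tok[1]
                elif tok[0] == "L":
                    L = int(tok[1])
                elif tok[0] == "POS":
                    pos_map[int(tok[1]) - 1] = int(tok[2])
                elif tok[0] == "H":
                    h_entries.append((int(tok[1]) - 1, tok[2], float(tok[3])))
                elif tok[0] == "J":
                    j_entries.append((int(tok[1]) - 1, int(tok[2]) - 1, tok[3], tok[4], float(tok[5])))
                else:
                    raise ValueError(f"unknown record {tok[0]!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed Potts parameter line ({exc})") from exc
    if alphabet is None or L is None:
        raise ValueError("model file must declare ALPHABET and L")
    q = len(alphabet)
    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    for i, a, v in h_entries:
        h[i, alphabet.index(a)] = v
    for i, j, a, b, v in j_entries:
        if not i < j:
            raise ValueError(f"couplings must have i < j, got {i + 1}, {j + 1}")
        J[i, j, alphabet.index(a), alphabet.index(b)] = v
    return PottsModel(alphabet=alphabet, h=h, J=J, position_map=pos_map or {i: i + 1 for i in range(L)})
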