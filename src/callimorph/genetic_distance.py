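"""Between-group mean nucleotide distances under the Tamura-Nei (1993) model.

Model parameters (base frequencies and the two transition/transversion rate
ratios) are estimated by maximizing a composite likelihood summed over all
sequence pairs, with a free divergence parameter per pair; distances use the
closed-form TN93 estimator with the shared parameters. Sites with a gap or
ambiguity in either member of a pair are excluded for that pair only
(pairwise deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .exceptions import ConvergenceError, SaturationError, ValidationError

__all__ = [
    "GroupedAlignment",
    "SubstitutionModelParams",
    "DistanceMatrix",
    "read_grouped_fasta",
    "pairwise_site_pattern_counts",
    "estimate_mcl_params",
    "pairwise_distance",
    "between_group_means",
    "tn93_rate_matrix",
    "tn93_transition_matrix",
]

BASES = "ACGT"
_BASE_CODES = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass
class GroupedAlignment:
    """Pre-aligned nucleotide sequences with a group (species) label per id."""

    sequences: dict[str, str]
    groups: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        unmapped = [i for i in self.sequences if i not in self.groups]
        if unmapped:
            raise ValidationError(f"ids missing from group map: {unmapped}")

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seq_id in self.sequences:
            out.setdefault(self.groups[seq_id], []).append(seq_id)
        return out


@dataclass(frozen=True)
class SubstitutionModelParams:
    """TN93 parameters: base frequencies (A,C,G,T) and the purine (kappa1)
    and pyrimidine (kappa2) transition/transversion rate ratios."""

    base_freqs: tuple[float, float, float, float]
    kappa1: float
    kappa2: float
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.min() <= 0 or abs(freqs.sum() - 1.0) > 1e-8:
            raise ValidationError("base frequencies must be positive and sum to 1")
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValidationError("kappas must be nonnegative")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray                      # symmetric, zero diagonal
    pair_counts: np.ndarray                 # cross pairs per entry
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.labels)), 2):
            rows.append(
                {
                    "group1": self.labels[i],
                    "group2": self.labels[j],
                    "distance": self.values[i, j],
                    "n_pairs": int(self.pair_counts[i, j]),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO


def read_grouped_fasta(path: str | Path, group_map: Mapping[str, str]) -> GroupedAlignment:
    """Read an aligned multi-FASTA; every record id must appear in group_map."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValidationError(f"no FASTA records in {path}")
    groups = {}
    for seq_id in sequences:
        if seq_id not in group_map:
            raise ValidationError(f"id missing from group map: {seq_id!r}")
        groups[seq_id] = group_map[seq_id]
    return GroupedAlignment(sequences=sequences, groups=groups)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column id -> group TSV (no header)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "group"], dtype=str)
    return dict(zip(frame["id"], frame["group"]))


# ---------------------------------------------------------------------------
# site patterns


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 for A/C/G/T, -1 for gap/ambiguity."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for code, byte in enumerate(_BASE_CODES):
        out[arr == byte] = code
    return out


def pairwise_site_pattern_counts(a: str, b: str) -> tuple[np.ndarray, int]:
    """4x4 site-pattern count matrix over sites where both residues are
    unambiguous A/C/G/T, plus the retained-site count."""
    if len(a) != len(b):
        raise ValidationError("sequences must have equal length")
    ea, eb = _encode(a), _encode(b)
    keep = (ea >= 0) & (eb >= 0)
    retained = int(keep.sum())
    if retained == 0:
        raise SaturationError("zero retained sites for this pair")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (ea[keep], eb[keep]), 1)
    return counts, retained


# ---------------------------------------------------------------------------
# TN93 machinery


def tn93_rate_matrix(params: SubstitutionModelParams, normalize: bool = True) -> np.ndarray:
    """TN93 instantaneous rate matrix over (A, C, G, T).

    Off-diagonal rate i->j is pi_j scaled by kappa1 for the purine
    transition, kappa2 for the pyrimidine transition, 1 for transversions;
    normalized so the expected substitution rate at stationarity is 1.
    """
    pi = np.asarray(params.base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if {i, j} == {0, 2}:      # A<->G
                rate *= params.kappa1
            elif {i, j} == {1, 3}:    # C<->T
                rate *= params.kappa2
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -(pi * np.diag(Q)).sum()
        if mu > 0:
            Q /= mu
    return Q


def _eigen_system(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible rate matrix via symmetrization."""
    d = np.sqrt(pi)
    S = (d[:, None] * Q) / d[None, :]      # D^{1/2} Q D^{-1/2}, symmetric
    S = (S + S.T) / 2.0
    lam, U = np.linalg.eigh(S)
    left = U.T * d[None, :]          # U^T D^{1/2}
    right = U / d[:, None]           # D^{-1/2} U
    return lam, right, left


def tn93_transition_matrix(params: SubstitutionModelParams, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the normalized TN93 rate matrix."""
    pi = np.asarray(params.base_freqs, dtype=float)
    Q = tn93_rate_matrix(params)
    lam, right, left = _eigen_system(Q, pi)
    P = (right * np.exp(lam * t)[None, :]) @ left
    return np.clip(P, 0.0, 1.0)


def _pair_loglik(counts: np.ndarray, pi: np.ndarray, eig, t: float) -> float:
    lam, right, left = eig
    P = (right * np.exp(lam * t)[None, :]) @ left
    with np.errstate(divide="ignore", invalid="ignore"):
        logjoint = np.log(np.clip(pi[:, None] * P, 1e-300, None))
    return float((counts * logjoint).sum())


def _profile_loglik(counts: np.ndarray, pi: np.ndarray, eig) -> float:
    """Max over the per-pair divergence t of the pair log-likelihood."""
    res = minimize_scalar(
        lambda t: -_pair_loglik(counts, pi, eig, t),
        bounds=(1e-8, 10.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return -float(res.fun)


def estimate_mcl_params(
    alignment: GroupedAlignment,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SubstitutionModelParams:
    """Composite-likelihood TN93 parameter estimate over all sequence pairs.

    Base frequencies come from pooled unambiguous sites; (kappa1, kappa2)
    maximize the sum over pairs of the profile log-likelihood (divergence
    maximized out per pair). Deterministic start at (1, 1).
    """
    seqs = list(alignment.sequences.values())
    if len(seqs) < 2:
        raise ValidationError("need at least 2 sequences")

    pooled = np.zeros(4, dtype=np.int64)
    for s in seqs:
        enc = _encode(s)
        pooled += np.bincount(enc[enc >= 0], minlength=4)
    if pooled.min() == 0:
        pooled = pooled + 1  # pseudocount guards degenerate compositions
    pi = pooled / pooled.sum()
    base_freqs = tuple(float(x) for x in pi)

    pair_counts = []
    any_diff = False
    for a, b in combinations(seqs, 2):
        counts, _ = pairwise_site_pattern_counts(a, b)
        pair_counts.append(counts)
        if counts.sum() - np.trace(counts) > 0:
            any_diff = True
    if not any_diff:
        warnings.warn("all sequences identical; kappas unidentifiable, returning 1,1")
        return SubstitutionModelParams(base_freqs, 1.0, 1.0, flags=("unidentifiable",))

    def objective(log_kappas: np.ndarray) -> float:
        k1, k2 = np.exp(log_kappas)
        params = SubstitutionModelParams(base_freqs, float(k1), float(k2))
        Q = tn93_rate_matrix(params)
        eig = _eigen_system(Q, pi)
        return -sum(_profile_loglik(c, pi, eig) for c in pair_counts)

    res = minimize(
        objective,
        x0=np.zeros(2),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError(f"kappa optimization did not converge: {res.message}")
    k1, k2 = np.exp(res.x)
    return SubstitutionModelParams(base_freqs, float(k1), float(k2))


# ---------------------------------------------------------------------------
# distances


def pairwise_distance(counts: np.ndarray, params: SubstitutionModelParams) -> float:
    """Closed-form TN93 distance from a pair's site-pattern counts, using the
    shared (composite-likelihood) base frequencies.

    Raises :class:`SaturationError` when a log argument is <= 0.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise SaturationError("no retained sites")
    piA, piC, piG, piT = params.base_freqs
    piR, piY = piA + piG, piC + piT

    P1 = (counts[0, 2] + counts[2, 0]) / total            # A<->G transitions
    P2 = (counts[1, 3] + counts[3, 1]) / total            # C<->T transitions
    transitions = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]
    Qv = (total - np.trace(counts) - transitions) / total  # transversions

    w1 = 1.0 - piR * P1 / (2.0 * piA * piG) - Qv / (2.0 * piR)
    w2 = 1.0 - piY * P2 / (2.0 * piT * piC) - Qv / (2.0 * piY)
    w3 = 1.0 - Qv / (2.0 * piR * piY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("distance undefined (saturated pair)")

    d = (
        -(2.0 * piA * piG / piR) * np.log(w1)
        - (2.0 * piT * piC / piY) * np.log(w2)
        - 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY) * np.log(w3)
    )
    return max(float(d), 0.0)


def between_group_means(
    alignment: GroupedAlignment,
    params: SubstitutionModelParams | None = None,
) -> DistanceMatrix:
    """Arithmetic mean of pairwise TN93 distances over all cross-group pairs.

    Saturated pairs are excluded from the mean with a warning; a group pair
    with no usable comparisons gets a missing (NaN) entry.
    """
    if params is None:
        params = estimate_mcl_params(alignment)
    members = alignment.group_members()
    labels = sorted(members)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    k = len(labels)
    values = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    warns: list[str] = []
    for i, j in combinations(range(k), 2):
        dists = []
        for a in members[labels[i]]:
            for b in members[labels[j]]:
                try:
                    cmat, _ = pairwise_site_pattern_counts(
                        alignment.sequences[a], alignment.sequences[b]
                    )
                    dists.append(pairwise_distance(cmat, params))
                except SaturationError:
                    warns.append(f"saturated pair {a}-{b} excluded")
        if dists:
            values[i, j] = values[j, i] = float(np.mean(dists))
        else:
            values[i, j] = values[j, i] = np.nan
            warns.append(f"no usable pairs between {labels[i]} and {labels[j]}")
        counts[i, j] = counts[j, i] = len(dists)
    return DistanceMatrix(labels=labels, values=values, pair_counts=counts, warnings=warns)
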