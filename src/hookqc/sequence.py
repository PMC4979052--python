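"""Positional-dependent nearest-neighbor (NN) sequence sensitivity model.

On GeneChip-type arrays the fluorescence intensity of a probe depends on its
25-mer sequence.  For the non-specific hybridization mode this dependence is
well described by a positional NN model: the decadic-log intensity increment
of a sequence xi is

    dA(xi) = sum_{k=1..24} sigma_k(xi^{k,k+1})

where xi^{k,k+1} is the dinucleotide at positions (k, k+1) and sigma is a
24 x 16 profile of sensitivity coefficients.  The profile is estimated by
least squares from probes that carry no specific signal ("absent" probes,
taken from the dimmest probe sets of the chip).

The model is over-parameterized (the 16 indicators at each position sum to
one); the gauge is fixed by requiring the 16 coefficients of every position to
sum to zero, which makes profiles comparable across chips.

The *maximum sensitivity amplitude*

    log(K_diff) = dA_max - dA_min

is the largest possible log-intensity difference between two probe sequences
under the fitted profile, i.e. the total strength of the chip's sequence
effect.  It is computed exactly over all 4^25 sequences by dynamic
programming over the base chain (the optimum need not be a homopolymer).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse

from .errors import InsufficientDataError, ValidationError
from .io import BASES, ChipData, encode_sequences

#: the 16 dinucleotides in code order (index = 4 * first + second)
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

N_POSITIONS = 24
N_DINUCLEOTIDES = 16
#: free parameters of the fit: 24 x 16 coefficients + intercept
N_FIT_PARAMETERS = N_POSITIONS * N_DINUCLEOTIDES + 1


@dataclasses.dataclass
class SensitivityProfile:
    """Positional NN sensitivity profile.

    ``sigma[k, d]`` is the decadic-log intensity contribution of dinucleotide
    ``DINUCLEOTIDES[d]`` at position ``k`` (0-based; position k covers
    sequence letters k and k+1).  ``intercept`` is the mean log10 intensity of
    the probe pool the profile was fitted on.
    """

    sigma: np.ndarray
    intercept: float = 0.0
    n_probes_fit: int = 0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[1] != N_DINUCLEOTIDES:
            raise ValidationError(
                f"sigma must be (positions, 16), got {self.sigma.shape}")
        if not np.isfinite(self.sigma).all():
            raise ValidationError("sigma contains non-finite entries")

    @property
    def n_positions(self) -> int:
        return self.sigma.shape[0]

    @property
    def sequence_length(self) -> int:
        return self.n_positions + 1

    def is_centered(self, tol: float = 1e-9) -> bool:
        """True when every position's 16 coefficients sum to zero (the
        identifiability gauge used by the fit)."""
        return bool(np.abs(self.sigma.sum(axis=1)).max(initial=0.0) <= tol)

    def delta_a_codes(self, codes: np.ndarray) -> np.ndarray:
        """dA for an (n, L) uint8 code array (vectorized Eq of the module
        docstring)."""
        if codes.shape[1] != self.sequence_length:
            raise ValidationError(
                f"sequence length {codes.shape[1]} does not match profile "
                f"({self.sequence_length})")
        dinuc = 4 * codes[:, :-1].astype(np.intp) + codes[:, 1:]
        return self.sigma[np.arange(self.n_positions)[None, :], dinuc].sum(axis=1)


def probe_delta_a(profile: SensitivityProfile, sequence: str) -> float:
    """Score a single probe sequence under the profile."""
    if len(sequence) != profile.sequence_length:
        raise ValidationError(
            f"sequence length {len(sequence)} does not match profile "
            f"({profile.sequence_length})")
    codes = encode_sequences([sequence])
    codes = codes[:, : profile.sequence_length]
    return float(profile.delta_a_codes(codes)[0])


# ---------------------------------------------------------------------------
# absent-probe selection and profile fitting
# ---------------------------------------------------------------------------

def select_absent_probes(chip: ChipData, quantile: float = 0.30,
                         min_multiple: int = 10) -> np.ndarray:
    """Indices of the PM probes used for the non-specific sensitivity fit.

    Takes all probes of the dimmest ``quantile`` fraction of probe sets (by
    set-mean log10 PM intensity).  These sets are dominated by non-specific
    hybridization, the mode the NN model describes.  Refuses when the pool is
    smaller than ``min_multiple`` times the 385 free fit parameters.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValidationError(f"quantile must be in (0, 1], got {quantile}")
    log_pm = np.log10(chip.pm)
    sums = np.bincount(chip.set_codes, weights=log_pm, minlength=chip.n_sets)
    means = sums / chip.set_sizes
    n_low = max(1, int(quantile * chip.n_sets))
    order = np.argsort(means, kind="stable")
    selected_sets = order[:n_low]
    mask = np.zeros(chip.n_sets, dtype=bool)
    mask[selected_sets] = True
    indices = np.nonzero(mask[chip.set_codes])[0]
    needed = min_multiple * N_FIT_PARAMETERS
    if indices.size < needed:
        raise InsufficientDataError(
            f"insufficient absent probes: {indices.size} selected but "
            f"{needed} required ({min_multiple} x {N_FIT_PARAMETERS} "
            f"free parameters)"
        )
    return indices


import functools


@functools.lru_cache(maxsize=4)
def _gauge_null_basis(n_positions: int) -> np.ndarray:
    """Orthonormal basis of the NN model's gauge (null) space in sigma space.

    Two coefficient matrices score every sequence identically when they
    differ by (i) a constant added to one position's 16 coefficients (the
    sequence always contributes exactly one dinucleotide per position; the
    constant belongs to the intercept) or (ii) a telescoping shift: add
    f(first base) to position j and subtract f(second base) from position
    j-1 — the two contributions cancel along any consistent base chain.
    These directions span the model's unidentifiable subspace (~4 + 7 per
    interior position); the canonical representative of a profile is its
    projection onto the orthogonal complement.
    """
    vectors = []
    for k in range(n_positions):
        v = np.zeros((n_positions, 16))
        v[k, :] = 1.0
        vectors.append(v.ravel())
    for j in range(1, n_positions):
        for b in range(4):
            v = np.zeros((n_positions, 16))
            v[j, 4 * b: 4 * b + 4] = 1.0     # first base of position j is b
            v[j - 1, b::4] -= 1.0            # second base of position j-1 is b
            vectors.append(v.ravel())
    basis = np.array(vectors).T
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum())
    return u[:, :rank]


def canonicalize_profile(sigma: np.ndarray,
                         intercept: float = 0.0) -> tuple[np.ndarray, float]:
    """Project sigma onto the canonical (minimum-norm) gauge.

    The removed component changes delta-A only by a constant, which is
    returned absorbed into the intercept.  Canonical profiles have zero
    per-position sums and are the unique representatives the fit recovers,
    so profiles become comparable across chips.
    """
    sigma = np.asarray(sigma, dtype=float)
    q = _gauge_null_basis(sigma.shape[0])
    flat = sigma.ravel()
    removed = q @ (q.T @ flat)
    canon = (flat - removed).reshape(sigma.shape)
    # delta-A shift of the removed part: evaluate on the poly-A sequence
    # (telescoping components score zero on every sequence, row constants
    # score their sum).
    shift = float(removed.reshape(sigma.shape)[:, 0].sum())
    return canon, intercept + shift


def indicator_design(codes: np.ndarray) -> tuple[scipy.sparse.csr_matrix,
                                                 np.ndarray]:
    """Sparse indicator design of the NN model for an (n, 25) code array:
    an intercept column plus one column per (position, dinucleotide) pair.
    Also returns the (n, 25) column-index array."""
    n = codes.shape[0]
    dinuc = 4 * codes[:, :-1].astype(np.intp) + codes[:, 1:]
    cols = np.empty((n, N_POSITIONS + 1), dtype=np.intp)
    cols[:, 0] = 0
    cols[:, 1:] = 1 + np.arange(N_POSITIONS)[None, :] * N_DINUCLEOTIDES + dinuc
    rows = np.repeat(np.arange(n, dtype=np.intp), N_POSITIONS + 1)
    data = np.ones(rows.shape[0])
    x = scipy.sparse.csr_matrix(
        (data, (rows, cols.ravel())), shape=(n, N_FIT_PARAMETERS))
    return x, cols


def fit_sensitivity_profile(chip: ChipData, probe_indices: np.ndarray,
                            ridge: float = 1e-6,
                            background: float = 0.0) -> SensitivityProfile:
    """Least-squares fit of log10(PM) = intercept + sum_k sigma_k(dinuc_k).

    Indicator encoding, one regressor per (position, dinucleotide) pair, a
    small ridge on the normal equations for numerical stability, and post-hoc
    projection onto the canonical gauge (:func:`canonicalize_profile`): the
    chain model is identifiable only up to per-position constants and
    telescoping shifts, so the unique minimum-norm representative is
    returned, with the constant mass absorbed into the intercept.

    ``background`` (an optical background estimate) is subtracted before
    taking logs: an additive offset comparable to the non-specific signal
    would otherwise compress the fitted coefficients, because the NN model is
    multiplicative on the hybridization-driven part of the intensity only.
    """
    probe_indices = np.asarray(probe_indices, dtype=np.intp)
    pm = chip.pm[probe_indices]
    if background > 0:
        pm = np.maximum(pm - background, 1e-3 * background)
    y = np.log10(pm)
    n = y.shape[0]
    x, cols = indicator_design(chip.codes[probe_indices])

    normal = (x.T @ x).toarray()
    rhs = x.T @ y
    normal[np.diag_indices_from(normal)] += ridge
    coef = scipy.linalg.solve(normal, rhs, assume_a="pos")

    counts = np.bincount(cols[:, 1:].ravel() - 1,
                         minlength=N_POSITIONS * N_DINUCLEOTIDES)
    unobserved = counts == 0
    if unobserved.any():
        k, d = np.divmod(np.nonzero(unobserved)[0][0], N_DINUCLEOTIDES)
        warnings.warn(
            f"{int(unobserved.sum())} (position, dinucleotide) pairs never "
            f"observed (first: position {int(k) + 1}, "
            f"{DINUCLEOTIDES[int(d)]}); their coefficients are set to 0",
            stacklevel=2)
        coef[1:][unobserved] = 0.0

    sigma, intercept = canonicalize_profile(
        coef[1:].reshape(N_POSITIONS, N_DINUCLEOTIDES), float(coef[0]))
    return SensitivityProfile(sigma=sigma, intercept=intercept, n_probes_fit=n)


# ---------------------------------------------------------------------------
# extremal sequences (maximum sensitivity amplitude)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExtremalResult:
    """Exact extremal probe sequences of a sensitivity profile."""

    max_sequence: str
    min_sequence: str
    delta_a_max: float
    delta_a_min: float

    @property
    def log_kdiff(self) -> float:
        return self.delta_a_max - self.delta_a_min


def _dp_extremum(sigma: np.ndarray, maximize: bool) -> tuple[str, float]:
    """Exact optimum of sum_k sigma[k, 4 b_k + b_{k+1}] over base chains.

    Backward dynamic program over the base at each position, followed by a
    greedy forward pass that picks the alphabetically smallest base at every
    tie, so the returned sequence is the lexicographically smallest optimum.
    """
    n_pos = sigma.shape[0]
    trans = sigma.reshape(n_pos, 4, 4)
    if not maximize:
        trans = -trans
    # suffix[b] = best achievable score from a base b at the current position
    suffix = np.zeros((n_pos + 1, 4))
    for k in range(n_pos - 1, -1, -1):
        suffix[k] = (trans[k] + suffix[k + 1][None, :]).max(axis=1)
    best = suffix[0].max()
    bases: list[int] = [int(np.nonzero(suffix[0] == best)[0][0])]
    for k in range(n_pos):
        b = bases[-1]
        scores = trans[k, b] + suffix[k + 1]
        bases.append(int(np.nonzero(scores == suffix[k, b])[0][0]))
    seq = "".join(BASES[b] for b in bases)
    value = best if maximize else -best
    return seq, float(value)


def extremal_sequences(profile: SensitivityProfile) -> ExtremalResult:
    """Exact maximization and minimization of dA over all sequences.

    Runs in O(L * 16) time via dynamic programming; ties are broken toward
    the alphabetically smallest base, so a zero profile yields ``"A" * L``.
    """
    max_seq, da_max = _dp_extremum(profile.sigma, maximize=True)
    min_seq, da_min = _dp_extremum(profile.sigma, maximize=False)
    return ExtremalResult(max_sequence=max_seq, min_sequence=min_seq,
                          delta_a_max=da_max, delta_a_min=da_min)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_profile(profile: SensitivityProfile, path: str | Path) -> None:
    """TSV: one row per position, 16 labeled dinucleotide columns; intercept
    and fit size in header comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# intercept={profile.intercept!r}\n")
        fh.write(f"# n_probes_fit={profile.n_probes_fit}\n")
        fh.write("position\t" + "\t".join(DINUCLEOTIDES) + "\n")
        for k in range(profile.n_positions):
            row = "\t".join(repr(float(v)) for v in profile.sigma[k])
            fh.write(f"{k + 1}\t{row}\n")


def read_profile(path: str | Path) -> SensitivityProfile:
    intercept = 0.0
    n_probes_fit = 0
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# intercept="):
                intercept = float(line.split("=", 1)[1])
            elif line.startswith("# n_probes_fit="):
                n_probes_fit = int(line.split("=", 1)[1])
            elif line.startswith("#") or line.startswith("position\t"):
                continue
            elif line:
                rows.append([float(v) for v in line.split("\t")[1:]])
    return SensitivityProfile(sigma=np.array(rows), intercept=intercept,
                              n_probes_fit=n_probes_fit)
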