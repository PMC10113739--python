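"""Mean-field direct coupling analysis (DCA) and Potts Hamiltonian scoring.

The family is modelled as a Boltzmann-like distribution over aligned
sequences S = (a_1 .. a_L),

    P(S) = (1/Z) exp( sum_{i<j} e_ij(a_i, a_j) + sum_i h_i(a_i) ),

with pairwise couplings e_ij and local fields h_i.  Parameters are inferred
by the mean-field (naive) approximation: the connected-correlation matrix
C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b), built over q-1 states per site with
the gap state as gauge reference, is inverted and e = -C^{-1}; fields follow
from the self-consistency condition that the model's independent-site
marginals reproduce the (pseudocounted, reweighted) single-site frequencies.
Sequences are scored by the Hamiltonian

    H(S) = - sum_{i<j} e_ij(a_i, a_j) - sum_i h_i(a_i),

so lower H means greater statistical compatibility with the family.
The partition function Z is never computed; only H and differences of H
(the delta-Hamiltonian of a mutant against a reference) are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .alphabet import ALPHABET, Alphabet
from .msa_io import Alignment


class PottsError(ValueError):
    pass


@dataclass
class FrequencyTables:
    """Reweighted, pseudocounted alignment statistics.

    f_i has shape (L, q); f_ij has shape (L, L, q, q) with the diagonal
    blocks f_ii(a, b) = delta_ab f_i(a).  n_eff is the effective sequence
    count (sum of reweighting weights).
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    n_eff: float
    pseudocount: float
    reweight_identity: Optional[float]

    @property
    def L(self) -> int:
        return self.f_i.shape[0]

    @property
    def q(self) -> int:
        return self.f_i.shape[1]


@dataclass
class PottsModel:
    """Couplings e_ij(a,b) (L, L, q, q) and fields h_i(a) (L, q).

    Invariants: e is pair-symmetric, e[i, j, a, b] == e[j, i, b, a]; the
    diagonal blocks e[i, i] are zero; all entries finite.
    """

    h: np.ndarray
    e: np.ndarray
    meta: dict = field(default_factory=dict)
    alphabet: Alphabet = field(default_factory=lambda: ALPHABET, repr=False)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if not (np.isfinite(self.h).all() and np.isfinite(self.e).all()):
            raise PottsError("non-finite Potts parameters")
        if self.e.shape != (self.L, self.L, self.q, self.q):
            raise PottsError("coupling tensor shape mismatch")
        if not np.allclose(self.e, self.e.transpose(1, 0, 3, 2), atol=atol):
            raise PottsError("couplings are not pair-symmetric")
        diag = self.e[np.arange(self.L), np.arange(self.L)]
        if not np.allclose(diag, 0.0, atol=atol):
            raise PottsError("diagonal coupling blocks must be zero")

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("h", data=self.h)
            f.create_dataset("e", data=self.e, compression="gzip")
            f.attrs["L"] = self.L
            f.attrs["q"] = self.q
            f.attrs["alphabet"] = self.alphabet.symbols
            for k, v in self.meta.items():
                if v is not None:
                    f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        with h5py.File(path, "r") as f:
            h = f["h"][...]
            e = f["e"][...]
            meta = {
                k: f.attrs[k] for k in f.attrs if k not in ("L", "q", "alphabet")
            }
        return cls(h=h, e=e, meta=meta)


def _sequence_weights(idx: np.ndarray, identity: float, block: int = 512) -> np.ndarray:
    """1 / (number of sequences with >= identity fractional identity), self included."""
    n, L = idx.shape
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, block):
        chunk = idx[start : start + block]  # (b, L)
        sim = (chunk[:, None, :] == idx[None, :, :]).mean(axis=2)  # (b, n)
        counts[start : start + block] = (sim >= identity).sum(axis=1)
    return 1.0 / counts


def compute_frequencies(
    onehot: np.ndarray,
    pseudocount: float = 0.5,
    reweight_identity: Optional[float] = 0.8,
) -> FrequencyTables:
    """Single-site and pair frequencies with reweighting and pseudocount.

    Each sequence is optionally down-weighted by the size of its >=80%
    identity neighbourhood (the mfDCA standard), then empirical frequencies
    are mixed with the uniform distribution:

        f_i  <- (1 - lam) f_emp_i  + lam / q
        f_ij <- (1 - lam) f_emp_ij + lam / q^2     (i != j)

    Diagonal blocks are set to f_ii(a, b) = delta_ab f_i(a) so that pair
    marginals match single-site frequencies exactly.
    """
    X = np.asarray(onehot, dtype=np.float64)
    n, L, q = X.shape
    if n < 2:
        raise PottsError("need at least 2 sequences to estimate frequencies")
    if not 0 <= pseudocount <= 1:
        raise PottsError("pseudocount must be in [0, 1]")

    if reweight_identity is not None:
        idx = X.argmax(axis=2)
        w = _sequence_weights(idx, reweight_identity)
    else:
        w = np.ones(n)
    n_eff = float(w.sum())

    Xw = X * w[:, None, None]
    f_i = Xw.sum(axis=0) / n_eff  # (L, q)
    flat = X.reshape(n, L * q)
    flat_w = Xw.reshape(n, L * q)
    f_ij = (flat_w.T @ flat).reshape(L, q, L, q).transpose(0, 2, 1, 3) / n_eff

    lam = pseudocount
    f_i = (1 - lam) * f_i + lam / q
    f_ij = (1 - lam) * f_ij + lam / (q * q)
    ii = np.arange(L)
    f_ij[ii, ii] = 0.0
    for a in range(q):
        f_ij[ii, ii, a, a] = f_i[:, a]

    return FrequencyTables(
        f_i=f_i,
        f_ij=f_ij,
        n_eff=n_eff,
        pseudocount=pseudocount,
        reweight_identity=reweight_identity,
    )


def infer_potts(freqs: FrequencyTables) -> PottsModel:
    """Mean-field inversion of the connected correlation matrix.

    Works in the gap-reference gauge: the correlation matrix is built over
    the first q-1 states of each site, inverted, and e = -C^{-1} mapped back
    to the full q-state tensor (entries touching the reference state are
    zero).  Fields solve the independent-site self-consistency

        h_i(a) = log f_i(a)/f_i(ref) - sum_{j != i} sum_b e_ij(a, b) f_j(b).
    """
    L, q = freqs.L, freqs.q
    r = q - 1  # reference state = last (gap)
    C = (
        freqs.f_ij[:, :, :r, :r]
        - freqs.f_i[:, None, :r, None] * freqs.f_i[None, :, None, :r]
    )
    C = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise PottsError(
            "correlation matrix is singular; increase the pseudocount"
        ) from exc

    e = np.zeros((L, L, q, q))
    e[:, :, :r, :r] = -invC.reshape(L, r, L, r).transpose(0, 2, 1, 3)
    ii = np.arange(L)
    e[ii, ii] = 0.0
    # exact pair symmetry despite roundoff in the inverse
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))

    with np.errstate(divide="ignore"):
        h = np.log(freqs.f_i) - np.log(freqs.f_i[:, -1:])
    # mean-field correction: subtract the coupling-weighted background
    h -= np.einsum("ijab,jb->ia", e, freqs.f_i)
    h -= h[:, -1:]  # keep h_i(ref) = 0 in the same gauge

    model = PottsModel(
        h=h,
        e=e,
        meta={
            "pseudocount": freqs.pseudocount,
            "reweight_identity": freqs.reweight_identity,
            "n_eff": freqs.n_eff,
        },
    )
    model.validate()
    return model


def _as_indices(
    seq: Union[str, Alignment, np.ndarray], model: PottsModel
) -> np.ndarray:
    """Coerce a sequence / alignment / index array to an (n, L) int matrix."""
    if isinstance(seq, str):
        if len(seq) != model.L:
            raise PottsError(f"sequence length {len(seq)} != model L={model.L}")
        return np.asarray([model.alphabet.encode(seq)])
    if isinstance(seq, Alignment):
        if seq.L != model.L:
            raise PottsError(f"alignment L={seq.L} != model L={model.L}")
        return seq.indices()
    arr = np.asarray(seq)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != model.L:
        raise PottsError(f"index array L={arr.shape[1]} != model L={model.L}")
    return arr.astype(np.int64)


def hamiltonian(
    seq: Union[str, Alignment, np.ndarray], model: PottsModel
) -> Union[float, np.ndarray]:
    """H(S) = -sum_{i<j} e_ij(a_i,a_j) - sum_i h_i(a_i); lower is better.

    Accepts a sequence string (returns a float), an Alignment, or an
    (n, L) integer index matrix (returns an (n,) vector).  Batched and
    per-sequence evaluation are numerically identical.
    """
    idx = _as_indices(seq, model)
    n, L = idx.shape
    H = -model.h[np.arange(L), idx].sum(axis=1)
    for i in range(L - 1):
        rows = model.e[i, i + 1 :]  # (L-i-1, q, q)
        H -= rows[np.arange(L - i - 1), idx[:, i, None], idx[:, i + 1 :]].sum(axis=1)
    if isinstance(seq, str):
        return float(H[0])
    return H


def delta_hamiltonian(
    seq: Union[str, Alignment, np.ndarray],
    ref: str,
    model: PottsModel,
) -> Union[float, np.ndarray]:
    """dH = H(seq) - H(ref); negative means more favorable than the reference."""
    return hamiltonian(seq, model) - hamiltonian(ref, model)


def zero_sum_gauge(e: np.ndarray) -> np.ndarray:
    """Transform couplings to the zero-sum gauge (for norm-based diagnostics)."""
    return (
        e
        - e.mean(axis=2, keepdims=True)
        - e.mean(axis=3, keepdims=True)
        + e.mean(axis=(2, 3), keepdims=True)
    )


def zero_sum_fields(model: PottsModel) -> np.ndarray:
    """Fields in the zero-sum gauge, centered per site.

    Moving the couplings to the zero-sum gauge shifts their per-row means
    into the fields; the result is the canonical parameterization for
    comparing field estimates across models (gauge alignment).
    """
    h = model.h + (
        model.e.mean(axis=3) - model.e.mean(axis=(2, 3))[:, :, None]
    ).sum(axis=1)
    return h - h.mean(axis=1, keepdims=True)


def coupling_norms(model: PottsModel, apc: bool = False) -> np.ndarray:
    """(L, L) Frobenius norms of zero-sum-gauge couplings.

    With ``apc=True`` the average-product correction is subtracted — a
    contact-prediction diagnostic only; the landscape never uses it.
    """
    ezs = zero_sum_gauge(model.e)
    F = np.sqrt((ezs**2).sum(axis=(2, 3)))
    np.fill_diagonal(F, 0.0)
    if apc:
        L = F.shape[0]
        row = F.sum(axis=1) / (L - 1)
        tot = F.sum() / (L * (L - 1))
        F = F - np.outer(row, row) / tot
        np.fill_diagonal(F, 0.0)
    return F


def score_table(
    aln: Alignment, model: PottsModel, ref: Optional[str] = None
) -> "pd.DataFrame":
    """Per-sequence H (and dH against `ref`) as a DataFrame ready for TSV."""
    import pandas as pd

    H = hamiltonian(aln, model)
    data = {"id": aln.ids, "H": H}
    if ref is not None:
        data["dH"] = H - hamiltonian(ref, model)
    return pd.DataFrame(data)
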