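"""Seeded generators of alignments with known ground truth.

Two family generators back every test in the package: Gibbs sampling from a
Potts model with known fields/couplings (so inference can be checked against
the truth), and mixture-of-profiles families with cluster labels (so latent
embeddings and label transfer can be checked against construction).  A q < 23
family uses the first q symbols of the canonical alphabet, so downstream
modules run unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import ALPHABET, Alphabet
from .msa_io import Alignment
from .potts import PottsModel


@dataclass
class SyntheticFamilySpec:
    """Ground-truth family parameters.

    coupling_pairs entries are (i, j) or (i, j, strength); pairs must
    satisfy i < j < L.  profile_concentration is the Dirichlet
    concentration of per-cluster position profiles — smaller values give
    more peaked, better-separated clusters.
    """

    L: int = 20
    q: int = 23
    n: int = 500
    n_clusters: int = 2
    coupling_pairs: Sequence[tuple] = field(default_factory=list)
    field_scale: float = 1.0
    coupling_scale: float = 1.0
    profile_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not 2 <= self.q <= len(ALPHABET):
            raise ValueError("q must be in [2, 23]")
        for pair in self.coupling_pairs:
            i, j = pair[0], pair[1]
            if not (0 <= i < j < self.L):
                raise ValueError(f"coupling pair {pair} must satisfy 0 <= i < j < L")


def restricted_alphabet(q: int) -> Alphabet:
    """Alphabet over the first q canonical symbols (gap excluded unless q=23)."""
    if q == len(ALPHABET):
        return ALPHABET
    return Alphabet(symbols=ALPHABET.symbols[:q], index={c: i for i, c in enumerate(ALPHABET.symbols[:q])})


def make_truth_potts(spec: SyntheticFamilySpec) -> PottsModel:
    """Random fields plus sparse couplings at the specified pairs only."""
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    h = rng.normal(0.0, spec.field_scale, size=(L, q))
    e = np.zeros((L, L, q, q))
    for pair in spec.coupling_pairs:
        i, j = pair[0], pair[1]
        scale = pair[2] if len(pair) > 2 else spec.coupling_scale
        block = rng.normal(0.0, scale, size=(q, q))
        e[i, j] = block
        e[j, i] = block.T
    model = PottsModel(
        h=h, e=e, meta={"synthetic": True, "seed": spec.seed},
        alphabet=restricted_alphabet(q),
    )
    model.validate()
    return model


def sample_potts_family(
    model: PottsModel,
    n: int,
    burn_in: int = 200,
    thin: int = 5,
    rng: Optional[np.random.Generator] = None,
    n_chains: int = 1,
) -> Alignment:
    """Single-site Gibbs sampling from P(S) proportional to exp(-H(S)).

    The conditional at position i is a softmax over
    h_i(a) + sum_{j != i} e_ij(a, a_j), matching the Hamiltonian's sign
    convention (lower H is more probable).  Sweeps run sequentially over
    positions; burn_in sweeps are discarded and every thin-th sweep kept.
    n_chains > 1 runs identical chains in parallel (vectorized) and
    interleaves their draws until n samples are collected.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    L, q = model.L, model.q
    # e indexed for fast conditional: e_cond[i, j, b, a] = e[i, j, a, b]
    e_cond = model.e.transpose(0, 1, 3, 2).copy()
    state = rng.integers(0, q, size=(n_chains, L))
    per_chain = -(-n // n_chains)  # ceil
    kept: list[np.ndarray] = []
    total_sweeps = burn_in + per_chain * thin
    jj = np.arange(L)
    for sweep in range(total_sweeps):
        for i in range(L):
            # logits[c, a] = h[i, a] + sum_j e[i, j, a, state[c, j]]
            contrib = e_cond[i][jj[None, :], state]  # (chains, L, q)
            logits = model.h[i][None, :] + contrib.sum(axis=1)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((n_chains, 1))
            state[:, i] = (p.cumsum(axis=1) > u).argmax(axis=1)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            kept.append(state.copy())
    samples = np.concatenate(kept, axis=0)[:n]
    seqs = [model.alphabet.decode(row) for row in samples]
    ids = [f"potts{k}" for k in range(len(seqs))]
    return Alignment(ids, seqs, alphabet=model.alphabet)


def make_clustered_family(
    spec: SyntheticFamilySpec,
) -> tuple[Alignment, list[int]]:
    """Mixture-of-profiles family with known cluster labels.

    Each cluster draws an independent per-position Dirichlet profile over
    the q symbols; sequences are sampled i.i.d. from their cluster profile.
    Low profile_concentration yields peaked, well-separated clusters (mean
    inter-cluster identity below intra-cluster identity by construction).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = restricted_alphabet(spec.q)
    profiles = rng.dirichlet(
        np.full(spec.q, spec.profile_concentration), size=(spec.n_clusters, spec.L)
    )  # (clusters, L, q)
    sizes = [spec.n // spec.n_clusters] * spec.n_clusters
    for k in range(spec.n % spec.n_clusters):
        sizes[k] += 1
    ids, seqs, labels = [], [], []
    counter = 0
    for c, size in enumerate(sizes):
        cum = profiles[c].cumsum(axis=1)  # (L, q)
        for _ in range(size):
            u = rng.random((spec.L, 1))
            idx = (cum > u).argmax(axis=1)
            ids.append(f"fam{counter}")
            seqs.append(alphabet.decode(idx))
            labels.append(c)
            counter += 1
    label_map = {i: f"cluster{c}" for i, c in zip(ids, labels)}
    return Alignment(ids, seqs, labels=label_map, alphabet=alphabet), labels
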