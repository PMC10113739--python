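"""Fidelity statistics and downstream-use protocols.

Covers the r20 higher-order marginal statistic (do generated sequences
reproduce the K-site motif frequencies of the family?), the paired-MSA
sampling protocol for external tree-topology comparison, nearest-neighbor
annotation transfer in latent space with GO-aware scoring, and combinatorial
mutant libraries with their landscape embedding report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.mixture import GaussianMixture

from .msa_io import Alignment, one_hot_encode
from .potts import PottsModel, hamiltonian
from .vae import VAEModel

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class R20Report:
    """Per-K lists of per-column-set correlations and their means."""

    correlations: dict[int, np.ndarray]
    n_sets: int
    top_motifs: int
    skipped: dict[int, int] = field(default_factory=dict)

    @property
    def mean_per_k(self) -> dict[int, float]:
        return {k: float(np.mean(v)) for k, v in self.correlations.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": list(self.correlations),
                "mean_r20": [self.mean_per_k[k] for k in self.correlations],
                "n_sets": [len(self.correlations[k]) for k in self.correlations],
                "n_skipped": [self.skipped.get(k, 0) for k in self.correlations],
            }
        )


def _motif_frequencies(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique motif rows and their frequencies within an (n, K) slice."""
    motifs, counts = np.unique(sub, axis=0, return_counts=True)
    return motifs, counts / sub.shape[0]


def _column_sets(
    L: int, K: int, n_sets: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    total = comb(L, K)
    if total <= n_sets:
        logger.warning(
            "only %d distinct %d-column sets exist (requested %d); using all",
            total, K, n_sets,
        )
        return list(combinations(range(L), K))
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < n_sets:
        cols = tuple(sorted(rng.choice(L, size=K, replace=False).tolist()))
        chosen.add(cols)
    return sorted(chosen)


def r20(
    generated: Alignment,
    reference: Alignment,
    K_values: Iterable[int] = (2, 3, 4, 5, 6, 7),
    n_sets: int = 3000,
    top_motifs: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> R20Report:
    """K-site marginal fidelity between a generated and a reference MSA.

    For each of n_sets random K-column sets, the reference's top
    `top_motifs` most frequent motifs (ties broken lexicographically) have
    their normalized frequencies compared between the two alignments by
    Pearson correlation; motifs absent from the generated MSA count as
    frequency zero.  A score of 1 for every K means perfect agreement of
    the K-site statistics.  Column sets whose motif-frequency vector has
    zero variance are skipped and counted.
    """
    if generated.L != reference.L:
        raise EvaluationError("generated and reference alignments differ in L")
    rng = rng if rng is not None else np.random.default_rng(0)
    ref_idx = reference.indices().astype(np.uint8)
    gen_idx = generated.indices().astype(np.uint8)
    L = reference.L
    correlations: dict[int, np.ndarray] = {}
    skipped: dict[int, int] = {}
    for K in sorted(K_values):
        if K > L:
            raise EvaluationError(f"K={K} exceeds alignment length L={L}")
        sets = _column_sets(L, K, n_sets, rng)
        vals = []
        n_skip = 0
        for cols in sets:
            cols = list(cols)
            motifs, ref_freq = _motif_frequencies(ref_idx[:, cols])
            # top motifs by count, ties by lexicographic motif order
            order = np.lexsort(motifs.T[::-1])
            motifs, ref_freq = motifs[order], ref_freq[order]
            top = np.argsort(-ref_freq, kind="stable")[:top_motifs]
            sel_motifs, sel_ref = motifs[top], ref_freq[top]
            gen_motifs, gen_freq = _motif_frequencies(gen_idx[:, cols])
            lookup = {m.tobytes(): f for m, f in zip(gen_motifs, gen_freq)}
            sel_gen = np.array([lookup.get(m.tobytes(), 0.0) for m in sel_motifs])
            if np.ptp(sel_ref) == 0 or np.ptp(sel_gen) == 0:
                if np.array_equal(sel_ref, sel_gen):
                    vals.append(1.0)  # identical (possibly flat) marginals
                else:
                    n_skip += 1
                continue
            vals.append(float(stats.pearsonr(sel_ref, sel_gen).statistic))
        correlations[K] = np.asarray(vals)
        if n_skip:
            skipped[K] = n_skip
            logger.info("r20 K=%d: skipped %d zero-variance column sets", K, n_skip)
    return R20Report(
        correlations=correlations, n_sets=n_sets, top_motifs=top_motifs, skipped=skipped
    )


@dataclass
class ProtocolMSAPair:
    """Paired generated/natural MSAs ready for external tree building."""

    generated: Alignment
    natural: Alignment
    cluster_assignments: np.ndarray
    retained_clusters: list[int]
    cutoff: float


def tree_protocol_sample(
    model: VAEModel,
    potts: PottsModel,
    aln: Alignment,
    n_clusters: int = 70,
    per_cluster: int = 10,
    cutoff: float = np.inf,
    rng: Optional[np.random.Generator] = None,
    exclude: Optional[Iterable[int]] = None,
    auto_exclude_smallest: int = 0,
    max_attempts_per_cluster: int = 10000,
) -> ProtocolMSAPair:
    """Cluster the latent embeddings and emit paired generated/natural MSAs.

    A Gaussian mixture with n_clusters components is fit to the training
    mu embeddings.  Components whose mean decodes to a sequence at or above
    the Hamiltonian cutoff are discarded (barrier-spanning clusters); an
    explicit `exclude` list of component indices is honored as well, and
    `auto_exclude_smallest` drops that many lowest-membership components
    up front (a deterministic stand-in for manual cluster curation).  Each
    retained cluster contributes per_cluster generated sequences (latent
    draws from the component, rejected while the argmax sequence scores at
    or above the cutoff, emitted as distribution-evaluated draws) and
    per_cluster natural member sequences, with ids "<cluster>_<0..9>".
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    exclude = set(exclude) if exclude is not None else set()
    X = one_hot_encode(aln)
    mu, _ = model.encode(X)
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(mu)
    assignments = gmm.predict(mu)
    if auto_exclude_smallest:
        counts = np.bincount(assignments, minlength=n_clusters)
        exclude |= set(np.argsort(counts, kind="stable")[:auto_exclude_smallest].tolist())

    retained = []
    for k in range(n_clusters):
        if k in exclude:
            continue
        mean_seq = model.decode(gmm.means_[k]).argmax(axis=1)
        if hamiltonian(mean_seq[None, :], potts)[0] < cutoff:
            retained.append(k)

    gen_ids, gen_seqs, nat_ids, nat_seqs = [], [], [], []
    for k in retained:
        members = np.flatnonzero(assignments == k)
        if len(members) < per_cluster:
            raise EvaluationError(
                f"cluster {k} has only {len(members)} members "
                f"(need {per_cluster})"
            )
        accepted = 0
        attempts = 0
        while accepted < per_cluster:
            if attempts >= max_attempts_per_cluster:
                raise EvaluationError(
                    f"cluster {k}: cutoff {cutoff} too strict "
                    f"({accepted}/{per_cluster} after {attempts} draws)"
                )
            z = rng.multivariate_normal(gmm.means_[k], gmm.covariances_[k])
            attempts += 1
            p = model.decode(z)
            if hamiltonian(p.argmax(axis=1)[None, :], potts)[0] >= cutoff:
                continue
            u = rng.random((model.L, 1))
            idx = (p.cumsum(axis=1) > u).argmax(axis=1)
            gen_ids.append(f"{k}_{accepted}")
            gen_seqs.append(model.alphabet.decode(idx))
            accepted += 1
        pick = rng.choice(members, size=per_cluster, replace=False)
        for j, row in enumerate(pick):
            nat_ids.append(f"{k}_{j}")
            nat_seqs.append(aln.seqs[row])

    return ProtocolMSAPair(
        generated=Alignment(gen_ids, gen_seqs, alphabet=model.alphabet),
        natural=Alignment(nat_ids, nat_seqs, alphabet=aln.alphabet),
        cluster_assignments=assignments,
        retained_clusters=retained,
        cutoff=float(cutoff),
    )


@dataclass
class AnnotationReport:
    """Nearest-neighbor label-transfer outcome.

    records has one row per query: (query id, nearest training id,
    distance, predicted label, truth label if known, verdict).  counts
    aggregates verdicts; in GO mode verdicts are exact/synonymous/missed,
    in plain label mode correct/coverage_error/incorrect.
    """

    records: pd.DataFrame
    counts: dict[str, int]

    @property
    def n_queries(self) -> int:
        return len(self.records)


def classify_go_prediction(
    predicted: str, truth: str, ontology_edges: Iterable[tuple[str, str]]
) -> str:
    """'exact' if equal, 'synonymous' if ancestor/descendant, else 'missed'.

    ontology_edges are (child, parent) pairs and must form a DAG; parent
    and child terms (direct or transitive) count as synonymous because leaf
    terms only refine their ancestors' meaning.
    """
    if predicted == truth:
        return "exact"
    G = nx.DiGraph(ontology_edges)
    if not nx.is_directed_acyclic_graph(G):
        raise EvaluationError("ontology edges contain a cycle")
    if predicted in G and truth in G:
        if nx.has_path(G, predicted, truth) or nx.has_path(G, truth, predicted):
            return "synonymous"
    return "missed"


def annotate_nearest(
    model: VAEModel,
    train_aln: Alignment,
    queries: Alignment,
    ontology_edges: Optional[Iterable[tuple[str, str]]] = None,
) -> AnnotationReport:
    """Transfer each query the label of its nearest training embedding.

    Distances are Euclidean between encoder mu coordinates; ties break by
    training order.  If the queries carry truth labels, each prediction is
    scored: with an ontology, exact/synonymous/missed; without, correct /
    coverage_error (truth label absent from the training label set) /
    incorrect.
    """
    if not train_aln.labels:
        raise EvaluationError("training alignment carries no labels")
    if queries.n == 0:
        return AnnotationReport(
            records=pd.DataFrame(
                columns=["query_id", "nearest_id", "distance", "predicted", "truth", "verdict"]
            ),
            counts={},
        )
    train_mu, _ = model.encode(one_hot_encode(
        Alignment(train_aln.ids, train_aln.seqs, alphabet=model.alphabet)))
    query_mu, _ = model.encode(one_hot_encode(
        Alignment(queries.ids, queries.seqs, alphabet=model.alphabet)))
    D = cdist(query_mu, train_mu)
    nearest = D.argmin(axis=1)  # first occurrence -> training-order tie-break
    train_labels = set(train_aln.labels.values())
    rows = []
    counts: dict[str, int] = {}
    edges = list(ontology_edges) if ontology_edges is not None else None
    for qi, ti in enumerate(nearest):
        qid = queries.ids[qi]
        tid = train_aln.ids[ti]
        pred = train_aln.labels.get(tid, "")
        truth = queries.labels.get(qid) if queries.labels else None
        verdict = None
        if truth is not None:
            if edges is not None:
                verdict = classify_go_prediction(pred, truth, edges)
            elif pred == truth:
                verdict = "correct"
            elif truth not in train_labels:
                verdict = "coverage_error"
            else:
                verdict = "incorrect"
            counts[verdict] = counts.get(verdict, 0) + 1
        rows.append(
            {
                "query_id": qid, "nearest_id": tid,
                "distance": float(D[qi, ti]), "predicted": pred,
                "truth": truth, "verdict": verdict,
            }
        )
    return AnnotationReport(records=pd.DataFrame(rows), counts=counts)


def combinatorial_mutants(
    ref: str,
    target: str,
    k: int,
    n_mutants: int,
    rng: Optional[np.random.Generator] = None,
) -> Alignment:
    """Random k-of-n combinatorial substitutions from `ref` toward `target`.

    The substitutable positions are exactly those where ref and target
    differ; each mutant picks k of them uniformly without replacement and
    takes the target residue there.  Chosen positions are recorded in the
    alignment's labels as a comma-joined list.
    """
    if len(ref) != len(target):
        raise EvaluationError("ref and target must have equal length")
    rng = rng if rng is not None else np.random.default_rng(0)
    diffs = [i for i, (a, b) in enumerate(zip(ref, target)) if a != b]
    if k > len(diffs):
        raise EvaluationError(
            f"k={k} exceeds the {len(diffs)} positions where ref and target differ"
        )
    ids, seqs, labels = [], [], {}
    ref_list = list(ref)
    for m in range(n_mutants):
        chosen = sorted(rng.choice(len(diffs), size=k, replace=False).tolist()) if k else []
        positions = [diffs[c] for c in chosen]
        seq = ref_list.copy()
        for pos in positions:
            seq[pos] = target[pos]
        mid = f"mut{m}"
        ids.append(mid)
        seqs.append("".join(seq))
        labels[mid] = ",".join(str(p) for p in positions)
    return Alignment(ids, seqs, labels=labels)


def mutant_report(
    model: VAEModel,
    potts: PottsModel,
    lib: Alignment,
    ref: str,
) -> pd.DataFrame:
    """Embed and score a mutant library against a reference.

    Returns one row per mutant: latent coordinates (encoder mu), Potts
    Hamiltonian, delta-Hamiltonian against the reference, and fractional
    identity to the reference.
    """
    if lib.L != model.L:
        raise EvaluationError(f"library L={lib.L} != model L={model.L}")
    X = one_hot_encode(Alignment(lib.ids, lib.seqs, alphabet=model.alphabet))
    mu, _ = model.encode(X)
    H = hamiltonian(lib, potts)
    H_ref = hamiltonian(ref, potts)
    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    identity = np.array(
        [
            (np.frombuffer(s.encode("ascii"), dtype=np.uint8) == ref_arr).mean()
            for s in lib.seqs
        ]
    )
    return pd.DataFrame(
        {
            "id": lib.ids,
            "z0": mu[:, 0],
            "z1": mu[:, 1],
            "H": H,
            "dH": H - H_ref,
            "identity_to_ref": identity,
        }
    )
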