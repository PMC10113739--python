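"""The latent generative landscape and its companion maps.

A rectangular grid over the two VAE latent dimensions is decoded pixel by
pixel into the maximum-probability sequence S*(z) and scored with the Potts
Hamiltonian H(S*), producing a fitness raster in which basins hold
family-compatible sequences and ridges act as barriers.  Companions:
the per-pixel average decoder entropy (how committed the decoder is at a
coordinate), the delta-Hamiltonian raster against a reference sequence's
decoded representation, the re-encoding vector field (decode then re-encode;
fixed points behave as attractors), rejection sampling of sequences from the
latent prior gated by a Hamiltonian cutoff, and the radial-exclusion
correlation between input-sequence and landscape Hamiltonians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from .msa_io import Alignment, one_hot_encode
from .potts import PottsModel, hamiltonian
from .vae import VAEModel


class LandscapeError(ValueError):
    pass


@dataclass(frozen=True)
class Grid:
    """Uniformly spaced n x n lattice over latent rectangle `bounds`.

    bounds = (z0_min, z0_max, z1_min, z1_max); lattice endpoints are
    included, so n = 2 gives the four corners.
    """

    bounds: tuple[float, float, float, float]
    n: int = 500

    def __post_init__(self) -> None:
        z0_min, z0_max, z1_min, z1_max = self.bounds
        if self.n < 2:
            raise LandscapeError("grid n must be >= 2")
        if not (z0_max > z0_min and z1_max > z1_min):
            raise LandscapeError("grid bounds must satisfy max > min on both axes")

    @property
    def z0(self) -> np.ndarray:
        return np.linspace(self.bounds[0], self.bounds[1], self.n)

    @property
    def z1(self) -> np.ndarray:
        return np.linspace(self.bounds[2], self.bounds[3], self.n)

    def centers(self) -> np.ndarray:
        """(n*n, 2) coordinates, row-major over (z1, z0)."""
        g0, g1 = np.meshgrid(self.z0, self.z1)
        return np.column_stack([g0.ravel(), g1.ravel()])


@dataclass
class Landscape:
    """Raster maps over a Grid: Hamiltonian always, the rest optional."""

    grid: Grid
    H: np.ndarray
    sequences: Optional[np.ndarray] = None  # (n, n, L) uint8 symbol indices
    entropy: Optional[np.ndarray] = None
    dH: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("H", data=self.H)
            if self.sequences is not None:
                f.create_dataset("sequences", data=self.sequences, compression="gzip")
            if self.entropy is not None:
                f.create_dataset("entropy", data=self.entropy)
            if self.dH is not None:
                f.create_dataset("dH", data=self.dH)
            f.attrs["bounds"] = self.grid.bounds
            f.attrs["n"] = self.grid.n
            for k, v in self.meta.items():
                if v is not None:
                    f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "Landscape":
        with h5py.File(path, "r") as f:
            grid = Grid(bounds=tuple(f.attrs["bounds"]), n=int(f.attrs["n"]))
            return cls(
                grid=grid,
                H=f["H"][...],
                sequences=f["sequences"][...] if "sequences" in f else None,
                entropy=f["entropy"][...] if "entropy" in f else None,
                dH=f["dH"][...] if "dH" in f else None,
                meta={k: f.attrs[k] for k in f.attrs if k not in ("bounds", "n")},
            )

    def to_frame(self) -> pd.DataFrame:
        """Flat (z0, z1, H[, entropy, dH]) table."""
        centers = self.grid.centers()
        data = {"z0": centers[:, 0], "z1": centers[:, 1], "H": self.H.ravel()}
        if self.entropy is not None:
            data["entropy"] = self.entropy.ravel()
        if self.dH is not None:
            data["dH"] = self.dH.ravel()
        return pd.DataFrame(data)


@dataclass
class VectorField:
    """Re-encoding displacement field: targets = encoder mu of each pixel's
    argmax sequence, vectors = targets - origins."""

    origins: np.ndarray
    targets: np.ndarray

    @property
    def vectors(self) -> np.ndarray:
        return self.targets - self.origins


def make_grid(
    model: VAEModel,
    training_mus: Optional[np.ndarray] = None,
    n: int = 500,
    margin: float = 0.10,
    bounds: Optional[tuple[float, float, float, float]] = None,
) -> Grid:
    """Grid over the training embeddings' bounding box plus a margin.

    Explicit `bounds` override the data-derived box.  The margin is a
    fraction of each axis range added on both sides.
    """
    if bounds is not None:
        return Grid(bounds=tuple(float(b) for b in bounds), n=n)
    if training_mus is None or len(training_mus) == 0:
        raise LandscapeError("need training embeddings or explicit bounds")
    mus = np.asarray(training_mus, dtype=np.float64)
    lo, hi = mus.min(axis=0), mus.max(axis=0)
    pad = margin * (hi - lo)
    return Grid(
        bounds=(lo[0] - pad[0], hi[0] + pad[0], lo[1] - pad[1], hi[1] + pad[1]), n=n
    )


def _decode_argmax_chunked(
    model: VAEModel, coords: np.ndarray, chunk: int = 8192
) -> np.ndarray:
    """(m, 2) coordinates -> (m, L) uint8 argmax symbol indices."""
    out = np.empty((len(coords), model.L), dtype=np.uint8)
    for s in range(0, len(coords), chunk):
        p = model.decode(coords[s : s + chunk])
        out[s : s + chunk] = p.argmax(axis=2)
    return out


def decoded_reference(model: VAEModel, reference: str) -> str:
    """S* of the reference: argmax sequence at the reference's encoded mu."""
    aln = Alignment(["ref"], [reference], alphabet=model.alphabet)
    mu, _ = model.encode(one_hot_encode(aln)[0])
    idx = _decode_argmax_chunked(model, mu[None, :])[0]
    return model.alphabet.decode(idx)


def build_landscape(
    model: VAEModel,
    potts: PottsModel,
    grid: Grid,
    reference: Optional[str] = None,
    keep_sequences: bool = False,
    chunk: int = 8192,
) -> Landscape:
    """Decode and Potts-score the argmax sequence at every grid center.

    With a reference sequence, a delta-Hamiltonian raster against the
    reference's decoded representation S* is added.  Batched and
    pixel-by-pixel evaluation give identical values.
    """
    if model.L != potts.L or len(model.alphabet) != potts.q:
        raise LandscapeError(
            f"VAE (L={model.L}, q={len(model.alphabet)}) and Potts "
            f"(L={potts.L}, q={potts.q}) models are incompatible"
        )
    coords = grid.centers()
    idx = _decode_argmax_chunked(model, coords, chunk=chunk)
    H = np.empty(len(coords))
    for s in range(0, len(coords), chunk):
        H[s : s + chunk] = hamiltonian(idx[s : s + chunk], potts)
    n = grid.n
    ls = Landscape(grid=grid, H=H.reshape(n, n), meta={"n_pixels": n * n})
    if keep_sequences:
        ls.sequences = idx.reshape(n, n, model.L)
    if reference is not None:
        ref_star = decoded_reference(model, reference)
        ls.dH = ls.H - hamiltonian(ref_star, potts)
        ls.meta["reference_decoded"] = ref_star
    return ls


def entropy_map(model: VAEModel, grid: Grid, chunk: int = 8192) -> np.ndarray:
    """Average per-residue decoder entropy at every pixel (nats).

    H_hat(z) = -(1/L) sum_i sum_a P_i(a) ln P_i(a), with 0 ln 0 = 0;
    bounded by [0, ln q] (ln 23 for the canonical alphabet).
    """
    coords = grid.centers()
    out = np.empty(len(coords))
    for s in range(0, len(coords), chunk):
        p = model.decode(coords[s : s + chunk])
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        out[s : s + chunk] = -plogp.sum(axis=(1, 2)) / model.L
    return out.reshape(grid.n, grid.n)


def reencode_field(model: VAEModel, grid: Grid, chunk: int = 8192) -> VectorField:
    """Decode each pixel's argmax sequence, re-encode it, take the mu."""
    coords = grid.centers()
    idx = _decode_argmax_chunked(model, coords, chunk=chunk)
    q = len(model.alphabet)
    targets = np.empty_like(coords)
    for s in range(0, len(coords), chunk):
        block = idx[s : s + chunk]
        onehot = np.zeros((len(block), model.L, q))
        onehot[
            np.arange(len(block))[:, None], np.arange(model.L)[None, :], block
        ] = 1.0
        mu, _ = model.encode(onehot)
        targets[s : s + chunk] = mu
    return VectorField(origins=coords, targets=targets)


def sample_filtered(
    model: VAEModel,
    potts: PottsModel,
    n_samples: int,
    cutoff: Optional[float] = None,
    scale: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    max_attempts: Optional[int] = None,
    batch: int = 1024,
) -> Alignment:
    """Rejection-sample sequences from the latent prior N(0, scale*I).

    A coordinate is accepted when its argmax sequence's Hamiltonian is
    below `cutoff` (None accepts everything); the emitted sequence is the
    distribution-evaluated one (an independent categorical draw per
    position), not the argmax.  Raises when `max_attempts` coordinates
    (default 1000 * n_samples) are exhausted before n_samples acceptances.

    Each record's label stores its accepted latent coordinate as
    "z0,z1,..." so acceptances can be re-audited against the cutoff.
    """
    if n_samples < 1:
        raise LandscapeError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    if max_attempts is None:
        max_attempts = 1000 * n_samples
    cut = np.inf if cutoff is None else float(cutoff)
    std = np.sqrt(scale)
    L, q = model.L, len(model.alphabet)
    seqs: list[str] = []
    coords: list[np.ndarray] = []
    attempts = 0
    while len(seqs) < n_samples:
        if attempts >= max_attempts:
            raise LandscapeError(
                f"Hamiltonian cutoff {cut} too strict: {len(seqs)}/{n_samples} "
                f"accepted after {attempts} draws"
            )
        m = min(batch, max_attempts - attempts)
        z = rng.normal(0.0, std, size=(m, model.config.latent_dim))
        attempts += m
        p = model.decode(z)
        star = p.argmax(axis=2)
        H = hamiltonian(star, potts)
        ok = np.flatnonzero(H < cut)
        if len(ok) == 0:
            continue
        u = rng.random((len(ok), L, 1))
        draws = (p[ok].cumsum(axis=2) > u).argmax(axis=2)
        for row, zk in zip(draws, z[ok]):
            seqs.append(model.alphabet.decode(row))
            coords.append(zk)
            if len(seqs) == n_samples:
                break
    ids = [f"gen{k}" for k in range(n_samples)]
    labels = {
        i: ",".join(f"{v:.8f}" for v in zk) for i, zk in zip(ids, coords)
    }
    return Alignment(ids, seqs, labels=labels, alphabet=model.alphabet)


def radial_exclusion_correlation(
    model: VAEModel,
    potts: PottsModel,
    aln: Alignment,
    radii: list[float],
) -> pd.DataFrame:
    """Input-vs-landscape Hamiltonian correlation, excluding a central disk.

    For each sequence, H_input is the Potts score of the sequence itself
    and H_map the score of the argmax sequence decoded at the sequence's
    encoded mu.  For each radius r the Pearson correlation is computed over
    sequences with ||mu|| > r (the high-entropy center is near the origin).
    Rows with fewer than 3 survivors report NaN.
    """
    X = one_hot_encode(aln)
    mu, _ = model.encode(X)
    H_input = hamiltonian(aln, potts)
    star = _decode_argmax_chunked(model, mu)
    H_map = hamiltonian(star, potts)
    norms = np.linalg.norm(mu, axis=1)
    rows = []
    for r in radii:
        mask = norms > r
        n_remaining = int(mask.sum())
        if n_remaining < 3:
            rows.append({"radius": r, "correlation": np.nan, "n_remaining": n_remaining})
            continue
        a, b = H_input[mask], H_map[mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            corr = np.nan if np.ptp(a) != np.ptp(b) else 1.0
        else:
            corr = float(stats.pearsonr(a, b).statistic)
        rows.append({"radius": r, "correlation": corr, "n_remaining": n_remaining})
    return pd.DataFrame(rows)
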