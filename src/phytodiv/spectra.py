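"""Fragmentation spectra, spectral cosine similarity and molecular networks.

MS/MS fragmentation spectra are diagnostic of molecular structure: two
compounds with many shared fragment ions are likely structural relatives.
This module reads/writes spectra (MGF), scores pairwise structural
similarity by peak-matched cosine, assembles the symmetric compound
similarity matrix epsilon used by the CSCS sample metrics, and builds the
molecular network (cosine threshold + mutual top-k rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
from pyteomics import mgf as _mgf

__all__ = [
    "FragmentationSpectrum", "SpectralLibrary", "SimilarityParams",
    "CompoundSimilarityMatrix", "MolecularNetwork",
    "read_mgf", "write_mgf", "cosine_similarity",
    "build_similarity_matrix", "build_network",
    "write_edge_list", "write_similarity_matrix", "read_similarity_matrix",
]


@dataclass
class FragmentationSpectrum:
    """A peak list for one compound.

    Peaks are normalized on construction: sorted ascending by m/z, exact
    duplicate m/z merged by summing intensities.  At least one peak with
    positive m/z and non-negative intensity is required.
    """

    compound_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.compound_id!r} has no peaks")
        if np.any(self.mz <= 0):
            raise ValueError(f"spectrum {self.compound_id!r} has non-positive m/z")
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.compound_id!r} has negative intensity")
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.compound_id!r} has non-positive precursor m/z")
        order = np.argsort(self.mz, kind="stable")
        mz, inten = self.mz[order], self.intensity[order]
        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            merged = np.zeros_like(uniq)
            np.add.at(merged, inverse, inten)
            mz, inten = uniq, merged
        self.mz, self.intensity = mz, inten

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectralLibrary:
    """Mapping compound_id -> spectrum."""

    spectra: dict[str, FragmentationSpectrum]

    def __post_init__(self) -> None:
        for cid, sp in self.spectra.items():
            if sp.compound_id != cid:
                raise ValueError(f"library key {cid!r} != spectrum id {sp.compound_id!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, cid: str) -> FragmentationSpectrum:
        return self.spectra[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.spectra

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.spectra)


@dataclass(frozen=True)
class SimilarityParams:
    """Peak-matching parameters (GNPS-style defaults: 0.02 Da tolerances,
    minimum 6 matched fragment peaks, square-root intensity weighting)."""

    fragment_tol: float = 0.02
    precursor_tol: float = 0.02
    min_matched_peaks: int = 6
    intensity_transform: str = "sqrt"

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")
        if self.intensity_transform not in ("raw", "sqrt"):
            raise ValueError("intensity_transform must be 'raw' or 'sqrt'")

    def transform(self, intensity: np.ndarray) -> np.ndarray:
        return np.sqrt(intensity) if self.intensity_transform == "sqrt" else intensity


@dataclass
class CompoundSimilarityMatrix:
    """Symmetric pairwise structural-similarity matrix epsilon in [0, 1],
    with unit diagonal, over an ordered list of compound ids."""

    compound_ids: list[str]
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        n = len(self.compound_ids)
        if len(set(self.compound_ids)) != n:
            raise ValueError("compound_ids must be unique")
        if self.epsilon.shape != (n, n):
            raise ValueError("epsilon shape does not match compound_ids")
        if not np.allclose(self.epsilon, self.epsilon.T, atol=1e-12):
            raise ValueError("epsilon must be symmetric")
        if not np.allclose(np.diag(self.epsilon), 1.0):
            raise ValueError("epsilon diagonal must be 1")
        if self.epsilon.min() < -1e-12 or self.epsilon.max() > 1 + 1e-12:
            raise ValueError("epsilon entries must lie in [0, 1]")
        np.clip(self.epsilon, 0.0, 1.0, out=self.epsilon)

    def index_of(self, cid: str) -> int:
        try:
            return self.compound_ids.index(cid)
        except ValueError:
            raise KeyError(f"compound {cid!r} not in similarity matrix") from None

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.index_of(c) for c in ids]
        return self.epsilon[np.ix_(idx, idx)]


@dataclass
class MolecularNetwork:
    """Undirected molecular network: nodes are compound ids; edges carry the
    cosine score and satisfy the construction threshold."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="cosine")
        return g


def read_mgf(path: str | Path) -> SpectralLibrary:
    """Read a Mascot Generic Format file into a library.

    One spectrum per ``BEGIN IONS`` block; ``TITLE`` is the compound id and
    ``PEPMASS`` the precursor m/z, both required.  Peaks are emitted sorted
    ascending by m/z.
    """
    spectra: dict[str, FragmentationSpectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for block_idx, entry in enumerate(reader):
            params = entry.get("params", {})
            title = params.get("title")
            if title is None or str(title).strip() == "":
                raise ValueError(f"MGF block {block_idx}: missing TITLE")
            cid = str(title).strip()
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"MGF block {block_idx} ({cid!r}): missing PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            mz = np.asarray(entry.get("m/z array", []), dtype=float)
            inten = np.asarray(entry.get("intensity array", []), dtype=float)
            try:
                spectrum = FragmentationSpectrum(
                    compound_id=cid, precursor_mz=precursor, mz=mz, intensity=inten)
            except ValueError as exc:
                raise ValueError(f"MGF block {block_idx} ({cid!r}): {exc}") from exc
            if cid in spectra:
                raise ValueError(f"MGF block {block_idx}: duplicate TITLE {cid!r}")
            spectra[cid] = spectrum
    return SpectralLibrary(spectra=spectra)


def write_mgf(library: SpectralLibrary, path: str | Path) -> None:
    """Write a library as MGF with TITLE=compound id, in sorted id order."""
    entries = []
    for cid in library.compound_ids:
        sp = library[cid]
        entries.append({
            "m/z array": sp.mz,
            "intensity array": sp.intensity,
            "params": {"title": cid, "pepmass": sp.precursor_mz},
        })
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


def _greedy_matches(
    a: FragmentationSpectrum, b: FragmentationSpectrum, tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one peak matching within ``tol`` Da.

    Candidate pairs are taken best-|delta m/z| first, ties broken by the
    lower (m/z_a, m/z_b) pair, and accepted only if neither peak is already
    matched — deterministic and order-independent.
    """
    diff = np.abs(a.mz[:, None] - b.mz[None, :])
    ii, jj = np.nonzero(diff <= tol)
    if ii.size == 0:
        return []
    order = np.lexsort((b.mz[jj], a.mz[ii], diff[ii, jj]))
    used_a = np.zeros(a.n_peaks, bool)
    used_b = np.zeros(b.n_peaks, bool)
    matches: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            matches.append((i, j))
    return matches


def cosine_similarity(
    a: FragmentationSpectrum,
    b: FragmentationSpectrum,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """Peak-matched cosine similarity between two spectra, in [0, 1].

    Matched-pair dot product of transformed intensities, normalized by each
    spectrum's norm over ALL of its peaks (unmatched peaks dilute the
    score).  Returns 0 if fewer than ``min_matched_peaks`` peaks match.
    Symmetric and invariant to global intensity rescaling.
    """
    matches = _greedy_matches(a, b, params.fragment_tol)
    if len(matches) < params.min_matched_peaks:
        return 0.0
    ta = params.transform(a.intensity)
    tb = params.transform(b.intensity)
    ia = np.fromiter((m[0] for m in matches), int, len(matches))
    ib = np.fromiter((m[1] for m in matches), int, len(matches))
    dot = float(np.dot(ta[ia], tb[ib]))
    norm = float(np.linalg.norm(ta) * np.linalg.norm(tb))
    if norm == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, dot / norm)))


def build_similarity_matrix(
    library: SpectralLibrary, params: SimilarityParams = SimilarityParams()
) -> CompoundSimilarityMatrix:
    """Pairwise cosine over a library (computed once per unordered pair);
    the diagonal is forced to exactly 1."""
    if len(library) == 0:
        raise ValueError("spectral library is empty")
    ids = library.compound_ids
    n = len(ids)
    eps = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = cosine_similarity(library[ids[i]], library[ids[j]], params)
            except ValueError as exc:
                raise ValueError(f"cosine({ids[i]!r}, {ids[j]!r}): {exc}") from exc
            eps[i, j] = eps[j, i] = s
    return CompoundSimilarityMatrix(compound_ids=ids, epsilon=eps)


def build_network(
    eps: CompoundSimilarityMatrix, min_cosine: float = 0.7, topk: int = 1000
) -> MolecularNetwork:
    """Threshold-plus-mutual-top-k molecular network.

    Candidate edges are pairs with epsilon >= ``min_cosine``; an edge is
    kept only if each endpoint ranks the other within its ``topk`` nearest
    neighbors by epsilon (ties broken by compound id order).
    """
    if topk < 1:
        raise ValueError("topk must be >= 1")
    ids = eps.compound_ids
    n = len(ids)
    e = eps.epsilon
    # rank[i, j] = position of j among i's neighbors, best epsilon first
    rank = np.empty((n, n), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = others[np.lexsort((others, -e[i, others]))]
        rank[i, order] = np.arange(n - 1)
        rank[i, i] = n  # never its own neighbor
    edges: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if e[i, j] >= min_cosine and rank[i, j] < topk and rank[j, i] < topk:
                edges.append((ids[i], ids[j], float(e[i, j])))
    return MolecularNetwork(nodes=list(ids), edges=edges)


def write_edge_list(network: MolecularNetwork, path: str | Path) -> None:
    """Tab-separated edge list: source, target, cosine."""
    lines = ["source\ttarget\tcosine"]
    for u, v, w in network.edges:
        lines.append(f"{u}\t{v}\t{w:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(network: MolecularNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(path))


def write_similarity_matrix(eps: CompoundSimilarityMatrix, path: str | Path) -> None:
    """Square TSV with a header row and leading id column."""
    with open(path, "w") as fh:
        fh.write("compound_id\t" + "\t".join(eps.compound_ids) + "\n")
        for i, cid in enumerate(eps.compound_ids):
            fh.write(cid + "\t" + "\t".join(f"{v:.10g}" for v in eps.epsilon[i]) + "\n")


def read_similarity_matrix(path: str | Path) -> CompoundSimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("similarity matrix rows and columns differ")
    return CompoundSimilarityMatrix(
        compound_ids=[str(c) for c in df.columns], epsilon=df.to_numpy(float))
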