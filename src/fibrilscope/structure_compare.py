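"""Fibril polymorph classification in structure space.

Protomers from different structures are mapped onto a common residue
numbering by pairwise global sequence alignment, truncated to a shared core
window (default residues 40-96), rigid-body superposed, embedded by PCA and
density-clustered with DBSCAN; per-residue RMSF within a cluster and
ensemble pairwise RMSD quantify intra-class variability.  Geometric helpers
measure salt-bridge distances and the cross-beta inter-protomer rise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from fibrilscope.spectra_io import ChainRecord, ProtomerEnsemble, StructureModel

DEFAULT_WINDOW = (40, 96)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# sequence mapping


def _aligner() -> Align.PairwiseAligner:
    # Needleman-Wunsch with match 1, mismatch -1, gap -2: enough to map
    # residue correspondence between near-identical fibril sequences.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


@dataclass
class ResidueMap:
    label: str
    mapping: dict[int, int]  # structure residue number -> reference number
    identity: float
    accepted: bool


def map_residues(chains: list[tuple[str, ChainRecord]], reference_sequence: str,
                 reference_first: int = 1,
                 min_identity: float = 0.5) -> list[ResidueMap]:
    """Map each chain's residues onto reference numbering by global alignment.

    Point mutations map by position; insertions/deletions are absorbed by
    the alignment.  Chains aligning at < ``min_identity`` are rejected
    (``accepted=False``) with their identity reported.
    """
    aligner = _aligner()
    out = []
    for label, chain in chains:
        numbers = sorted(chain.residues)
        seq = "".join(chain.residues[n].type for n in numbers)
        alignment = aligner.align(reference_sequence, seq)[0]
        mapping: dict[int, int] = {}
        n_match = 0
        n_aligned = 0
        for (r0, r1), (q0, q1) in zip(*alignment.aligned):
            for k in range(r1 - r0):
                ref_pos = r0 + k
                q_pos = q0 + k
                mapping[numbers[q_pos]] = reference_first + ref_pos
                n_aligned += 1
                if reference_sequence[ref_pos] == seq[q_pos]:
                    n_match += 1
        identity = n_match / max(1, n_aligned)
        out.append(ResidueMap(label, mapping, identity, identity >= min_identity))
    return out


# ---------------------------------------------------------------------------
# aligned coordinate matrix


@dataclass
class AlignedCoordinates:
    """One row per protomer: concatenated CA x,y,z over the residue window."""

    labels: list[str]
    residue_window: tuple[int, int]
    matrix: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        first, last = self.residue_window
        expected = 3 * (last - first + 1)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != expected:
            raise ValueError(
                f"matrix has {m.shape[1] if m.ndim == 2 else '?'} columns, "
                f"expected {expected} for window {self.residue_window}"
            )
        if m.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        self.matrix = m

    @property
    def n_residues(self) -> int:
        first, last = self.residue_window
        return last - first + 1

    def rows_as_coords(self) -> np.ndarray:
        return self.matrix.reshape(len(self.labels), self.n_residues, 3)


def extract_ca_window(chains: list[tuple[str, ChainRecord]],
                      window: tuple[int, int] = DEFAULT_WINDOW,
                      maps: list[ResidueMap] | None = None) -> AlignedCoordinates:
    """Build the CA coordinate matrix over the core window.

    Chains missing any CA inside the window (after renumbering through
    ``maps`` if given) are excluded and reported, not silently dropped.
    """
    first, last = window
    rows, labels, excluded = [], [], []
    for k, (label, chain) in enumerate(chains):
        if maps is not None:
            rmap = maps[k].mapping
            if not maps[k].accepted:
                excluded.append(label)
                continue
            renum = {rmap[n]: r for n, r in chain.residues.items() if n in rmap}
        else:
            renum = chain.residues
        coords = []
        ok = True
        for num in range(first, last + 1):
            res = renum.get(num)
            ca = res.atoms.get("CA") if res is not None else None
            if ca is None:
                ok = False
                break
            coords.append(ca.pos)
        if not ok:
            excluded.append(label)
            continue
        rows.append(np.concatenate(coords))
        labels.append(label)
    if not rows:
        raise ValueError(f"no chain covers the full window {window} with CA atoms")
    return AlignedCoordinates(labels, window, np.array(rows), excluded)


# ---------------------------------------------------------------------------
# superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |R P + t - Q|.

    Standard SVD solution with the determinant sign fix (no reflections).
    """
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rmsd_after_fit(P: np.ndarray, Q: np.ndarray) -> float:
    R, t = kabsch(P, Q)
    diff = (P @ R.T + t) - Q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def superpose(coords: AlignedCoordinates, tol: float = 1e-6,
              max_iter: int = 100) -> AlignedCoordinates:
    """Iteratively fit every row onto the evolving mean structure.

    Converges when the mean row RMSD changes by < ``tol`` Angstrom; the
    output frame is centred (zero mean translation).  Degenerate (collinear)
    coordinate sets are rejected.
    """
    X = coords.rows_as_coords().copy()
    n_rows = X.shape[0]
    if n_rows < 2:
        raise ValueError("superposition needs >= 2 rows")
    ref = X[0] - X[0].mean(axis=0)
    if np.linalg.matrix_rank(ref) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    prev = np.inf
    for _ in range(max_iter):
        for k in range(n_rows):
            R, t = kabsch(X[k], ref)
            X[k] = X[k] @ R.T + t
        mean = X.mean(axis=0)
        score = float(np.mean(np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=1))))
        if abs(prev - score) < tol:
            break
        prev = score
        ref = mean
    X -= X.mean(axis=(0, 1))
    return AlignedCoordinates(coords.labels, coords.residue_window,
                              X.reshape(n_rows, -1), coords.excluded)


# ---------------------------------------------------------------------------
# embedding, clustering, fluctuation


@dataclass
class PCAEmbedding:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    components: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.components + self.mean


def pca_embed(fitted: AlignedCoordinates, n_components: int = 2) -> PCAEmbedding:
    """Centered PCA of the fitted coordinate rows."""
    n_rows = fitted.matrix.shape[0]
    if n_rows < 3:
        raise ValueError("PCA needs >= 3 rows")
    if n_components >= n_rows:
        raise ValueError(f"n_components {n_components} must be < n_rows {n_rows}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(fitted.matrix)
    return PCAEmbedding(scores, pca.explained_variance_ratio_, pca.mean_, pca.components_)


def kdist_elbow_eps(scores: np.ndarray, min_pts: int = 3) -> float:
    """Default DBSCAN eps from the sorted k-nearest-neighbour distance curve.

    k = min_pts - 1 (a point is core once min_pts points, itself included,
    sit within eps).  A curve spanning less than a factor of 5 has a single
    density regime, so eps is its maximum (every point becomes core);
    otherwise eps sits at the knee, the point of maximum perpendicular
    distance to the first-to-last chord (kneedle-style).
    """
    from scipy.spatial.distance import cdist

    d = cdist(scores, scores)
    k = max(1, min(min_pts - 1, len(scores) - 1))
    kdist = np.sort(np.sort(d, axis=1)[:, k])
    n = len(kdist)
    if kdist[-1] <= 0:
        return 1.0
    if n < 3 or kdist[-1] == kdist[0]:
        return float(kdist[-1])
    if kdist[-1] <= 5.0 * max(float(np.median(kdist)), 1e-12):
        return float(kdist[-1])
    x = np.arange(n, dtype=float)
    p0 = np.array([0.0, kdist[0]])
    p1 = np.array([n - 1.0, kdist[-1]])
    seg = p1 - p0
    seg /= np.linalg.norm(seg)
    pts = np.stack([x, kdist], axis=1) - p0
    dist = np.abs(pts[:, 0] * seg[1] - pts[:, 1] * seg[0])
    return float(kdist[int(np.argmax(dist))])


def dbscan_cluster(scores: np.ndarray, eps: float | None = None,
                   min_pts: int = 3) -> np.ndarray:
    """Standard DBSCAN labels; noise = -1.  eps defaults to the k-dist elbow."""
    scores = np.asarray(scores, dtype=float)
    if eps is None:
        eps = kdist_elbow_eps(scores, min_pts)
    if eps <= 0:
        raise ValueError("eps must be positive")
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(scores)


def per_residue_rmsf(fitted: AlignedCoordinates,
                     members: list[int] | None = None) -> np.ndarray:
    """RMSF_r = sqrt(mean over members of |x_r - xbar_r|^2), Angstrom."""
    X = fitted.rows_as_coords()
    if members is not None:
        X = X[members]
    if X.shape[0] < 2:
        raise ValueError("RMSF needs >= 2 members")
    mean = X.mean(axis=0)
    return np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# ensemble geometry


def _select_atoms(model: StructureModel, residue_range: tuple[int, int],
                  atoms: str) -> list[tuple[str, int, str]]:
    first, last = residue_range
    keys = []
    for cid, chain in model.chains.items():
        for num in range(first, last + 1):
            res = chain.residues.get(num)
            if res is None:
                continue
            for name, atom in res.atoms.items():
                if atoms == "backbone" and name not in BACKBONE_ATOMS:
                    continue
                if atoms == "heavy" and atom.element == "H":
                    continue
                keys.append((cid, num, name))
    return keys


def ensemble_pairwise_rmsd(ens: ProtomerEnsemble, residue_range: tuple[int, int],
                           atoms: str = "backbone") -> float:
    """Mean pairwise RMSD over all unordered model pairs, Angstrom.

    Every pair is superposed independently on the selected atoms
    (matchmaker-like convention) before the RMSD is computed; atoms missing
    from any model are excluded consistently across all models.
    """
    if atoms not in ("backbone", "heavy"):
        raise ValueError("atoms must be 'backbone' or 'heavy'")
    if len(ens.models) < 2:
        raise ValueError("pairwise RMSD needs >= 2 models")
    common = set(_select_atoms(ens.models[0], residue_range, atoms))
    for model in ens.models[1:]:
        common &= set(_select_atoms(model, residue_range, atoms))
    if not common:
        raise ValueError(f"no common {atoms} atoms in range {residue_range}")
    keys = sorted(common)
    stacks = []
    for model in ens.models:
        stacks.append(np.array([model.chains[c].residues[n].atoms[a].pos for c, n, a in keys]))
    vals = []
    for i in range(len(stacks)):
        for j in range(i + 1, len(stacks)):
            vals.append(rmsd_after_fit(stacks[i], stacks[j]))
    return float(np.mean(vals))


def salt_bridge_distance(model: StructureModel, res1: int, atom1: str,
                         res2: int, atom2: str,
                         chain1: str, chain2: str) -> float:
    """Euclidean distance between two named atoms, e.g. E46 CD - K80 CE."""

    def fetch(cid, num, name):
        chain = model.chains.get(cid)
        res = chain.residues.get(num) if chain is not None else None
        atom = res.atoms.get(name) if res is not None else None
        if atom is None:
            raise KeyError(f"atom chain {cid} residue {num} {name} not found")
        return atom.pos

    return float(np.linalg.norm(fetch(chain1, res1, atom1) - fetch(chain2, res2, atom2)))


def protomer_rise(model: StructureModel) -> float:
    """Mean translation between adjacent chains along the fibril axis.

    The axis is the principal axis of the stack of chain centroids; the
    rise is the mean projection of adjacent centroid-to-centroid vectors
    onto it.  Cross-beta amyloids show the characteristic ~4.7 A spacing.
    """
    cents = []
    for chain in model.chains.values():
        pts = np.array([a.pos for res in chain.residues.values() for a in res.atoms.values()])
        cents.append(pts.mean(axis=0))
    if len(cents) < 2:
        raise ValueError("protomer rise needs >= 2 chains")
    cents = np.array(cents)
    centered = cents - cents.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    diffs = np.diff(cents, axis=0)
    return float(np.mean(np.abs(diffs @ axis)))
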