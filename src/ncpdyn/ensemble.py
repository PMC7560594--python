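"""Conformational ensemble analysis: RMSD clustering and internal-coordinate PCA.

Clustering follows common trajectory-analysis practice: all-against-all
heavy-atom RMSD of the damaged 13-bp section after per-pair optimal
superposition, average-linkage hierarchical clustering cut at a distance
threshold (default 2.5 Å) or into a fixed number of clusters, cluster
occupancies as percentages of all frames, and medoid representatives.

The PCA operates on internal coordinates — the inverse distances between
the geometric centres (unweighted heavy-atom means) of residue pairs —
rather than Cartesian coordinates, making it exactly invariant under
rigid-body motion.  Per-residue importance sums, over the first
``n_components`` principal components, the squared loadings of every pair
feature containing the residue, weighted by the component's eigenvalue
share, then normalizes the result to percentages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure import SelectionError, Structure, Trajectory, select_atoms


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray,
    atom_sel: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates and the RMSD over the fitted
    atoms.  The rotation is proper (determinant +1); reflections are never
    applied.  Requires >= 3 non-collinear fit atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if atom_sel is None else np.asarray(atom_sel)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    m = mobile[sel]
    r = reference[sel]
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise ValueError("superposition atoms are collinear")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = (mobile - m.mean(axis=0)) @ rot.T + r.mean(axis=0)
    rmsd = float(np.sqrt(((moved[sel] - r) ** 2).sum() / sel.size))
    return moved, rmsd


@dataclass
class RMSDMatrix:
    """Condensed pairwise RMSD matrix (Å) after per-pair superposition.

    Because every pair is superposed independently, the triangle inequality
    is not guaranteed; the matrix is a dissimilarity, not a metric.
    """

    n_frames: int
    condensed: np.ndarray
    atom_selection: str = ""

    def full(self) -> np.ndarray:
        if self.n_frames == 1:
            return np.zeros((1, 1))
        return squareform(self.condensed)


def pairwise_rmsd(traj: Trajectory,
                  atom_sel: np.ndarray | None = None,
                  description: str = "") -> RMSDMatrix:
    """All-against-all minimum RMSD over the selected atoms.

    Each frame pair is optimally superposed (Kabsch) before the RMSD is
    taken.  Implemented with batched 3x3 cross-covariances and SVDs so that
    a few thousand frames stay tractable.
    """
    sel = (np.arange(traj.topology.n_atoms) if atom_sel is None
           else np.asarray(atom_sel, dtype=int))
    if sel.size < 3:
        raise SelectionError("pairwise RMSD needs >= 3 selected atoms")
    n = traj.n_frames
    x = traj.frames[:, sel].astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    traces = np.einsum("fij,fij->f", x, x)
    n_atoms = sel.size
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n - 1):
        rest = x[i + 1:]
        h = np.einsum("ax,jay->jxy", x[i], rest)
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("jxy,jyz->jxz", u, vt))
        s_eff = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
        msd = (traces[i] + traces[i + 1:] - 2.0 * s_eff) / n_atoms
        out[pos:pos + rest.shape[0]] = np.sqrt(np.maximum(msd, 0.0))
        pos += rest.shape[0]
    return RMSDMatrix(n, out, description)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray                  # per-frame cluster id (1-based)
    occupancy: dict[int, float]         # cluster id -> percent of frames
    medoid: dict[int, int]              # cluster id -> frame index


def representative_frame(members: np.ndarray, matrix: RMSDMatrix) -> int:
    """Medoid: the member minimizing mean RMSD to the other members.

    Ties are broken toward the lower frame index.
    """
    members = np.sort(np.asarray(members, dtype=int))
    if members.size == 0:
        raise ValueError("empty cluster has no representative")
    if members.size == 1:
        return int(members[0])
    sub = matrix.full()[np.ix_(members, members)]
    mean_rmsd = sub.sum(axis=1) / (members.size - 1)
    return int(members[int(np.argmin(mean_rmsd))])


def cluster_frames(matrix: RMSDMatrix, *, method: str = "average",
                   epsilon: float | None = None,
                   k: int | None = None) -> ClusterResult:
    """Hierarchical clustering of the RMSD matrix.

    Cut either at distance threshold ``epsilon`` (default 2.5 Å when
    neither criterion is given) or into ``k`` clusters.  Output is
    deterministic for a given matrix and parameters.
    """
    if epsilon is not None and epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    if epsilon is not None and k is not None:
        raise ValueError("give either epsilon or k, not both")
    if epsilon is None and k is None:
        epsilon = 2.5
    n = matrix.n_frames
    if n == 1:
        labels = np.array([1])
    elif np.allclose(matrix.condensed, 0.0):
        labels = np.ones(n, dtype=int)
    else:
        z = linkage(matrix.condensed, method=method)
        if k is not None:
            labels = fcluster(z, t=k, criterion="maxclust")
        else:
            labels = fcluster(z, t=epsilon, criterion="distance")
    occupancy = {
        int(c): 100.0 * float(np.count_nonzero(labels == c)) / n
        for c in np.unique(labels)
    }
    medoid = {
        c: representative_frame(np.flatnonzero(labels == c), matrix)
        for c in occupancy
    }
    return ClusterResult(labels, occupancy, medoid)


# ---------------------------------------------------------------------------
# Internal-coordinate PCA
# ---------------------------------------------------------------------------

def residue_centers(traj: Trajectory,
                    residues: list[tuple[str, int]]) -> np.ndarray:
    """(n_frames, n_residues, 3) unweighted heavy-atom geometric centres."""
    centers = np.empty((traj.n_frames, len(residues), 3))
    for j, (chain, resnum) in enumerate(residues):
        idx = select_atoms(traj.topology, chain=chain, residue_number=resnum,
                           heavy_only=True,
                           required=f"heavy atoms of {chain}:{resnum}")
        centers[:, j] = traj.frames[:, idx].mean(axis=1)
    return centers


def pair_features(
    traj: Trajectory, residue_sel: list[tuple[str, int]],
) -> tuple[np.ndarray, list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Inverse-distance features between residue geometric centres.

    Returns ``(features, pairs)`` where ``features[f, p] = 1 / d(center_i,
    center_j)`` in Å⁻¹ for the p-th unordered pair, pairs ordered
    lexicographically over the selection order: (0,1), (0,2), ... (n-2,n-1).
    """
    if len(residue_sel) < 2:
        raise ValueError("need at least two residues for pair features")
    centers = residue_centers(traj, residue_sel)
    pairs = list(itertools.combinations(range(len(residue_sel)), 2))
    feats = np.empty((traj.n_frames, len(pairs)))
    for p, (i, j) in enumerate(pairs):
        d = np.linalg.norm(centers[:, i] - centers[:, j], axis=1)
        zero = np.flatnonzero(d < 1e-9)
        if zero.size:
            raise ValueError(
                f"coincident residue centres at frame {int(zero[0])} for "
                f"pair {residue_sel[i]}–{residue_sel[j]}"
            )
        feats[:, p] = 1.0 / d
    return feats, [(residue_sel[i], residue_sel[j]) for i, j in pairs]


@dataclass
class PCAModel:
    feature_pairs: list
    feature_mean: np.ndarray
    eigenvalues: np.ndarray       # descending, clipped at 0
    eigenvectors: np.ndarray      # (n_components, n_features) rows
    degenerate: bool = False      # all-zero covariance

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def pca_fit(features: np.ndarray, feature_pairs: list | None = None) -> PCAModel:
    """Principal components of the mean-centred feature covariance.

    Eigenvalues are sorted descending; tiny negative values from the
    symmetric eigensolver are clipped to zero.  A model fitted on constant
    features is flagged ``degenerate``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("PCA needs a (n_frames >= 2, n_features) matrix")
    mean = features.mean(axis=0)
    centered = features - mean
    cov = centered.T @ centered / (features.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    return PCAModel(
        feature_pairs if feature_pairs is not None
        else list(range(features.shape[1])),
        mean, evals, evecs,
        degenerate=bool(np.all(evals < 1e-12)),
    )


@dataclass
class ResidueImportance:
    per_residue: dict[tuple[str, int], float]   # residue -> percent
    n_components_used: int


def residue_importance(
    model: PCAModel,
    n_components: int = 10,
    *,
    weighting: str = "eigenvalue",
    loading_power: str = "squared",
) -> ResidueImportance:
    """Map principal-component loadings back onto residues as percentages.

    For each residue r the raw score is
    ``sum_c w_c * sum_{features f containing r} loading(c, f)**2`` over the
    first ``n_components`` components, with ``w_c`` the eigenvalue share of
    component c among those used (``weighting="uniform"`` uses equal
    weights; ``loading_power="abs"`` uses absolute loadings instead of
    squares).  Scores are normalized to sum to 100; each pair feature
    contributes to both of its residues.
    """
    if n_components > model.n_components:
        raise ValueError(
            f"n_components={n_components} exceeds available "
            f"{model.n_components}"
        )
    if weighting not in ("eigenvalue", "uniform"):
        raise ValueError("weighting must be 'eigenvalue' or 'uniform'")
    if loading_power not in ("squared", "abs"):
        raise ValueError("loading_power must be 'squared' or 'abs'")
    evals = model.eigenvalues[:n_components]
    total = evals.sum()
    if weighting == "eigenvalue":
        if total <= 0:
            raise ValueError("degenerate model: all eigenvalues are zero")
        weights = evals / total
    else:
        weights = np.full(n_components, 1.0 / n_components)
    load = model.eigenvectors[:n_components]
    contrib = load ** 2 if loading_power == "squared" else np.abs(load)
    feature_score = weights @ contrib          # per-feature
    raw: dict[tuple[str, int], float] = {}
    for f, pair in enumerate(model.feature_pairs):
        for res in pair:
            raw[res] = raw.get(res, 0.0) + float(feature_score[f])
    norm = sum(raw.values())
    if norm <= 0:
        raise ValueError("degenerate model: zero total importance")
    return ResidueImportance(
        {res: 100.0 * v / norm for res, v in raw.items()}, n_components
    )


def paint_importance(structure: Structure,
                     importance: ResidueImportance) -> Structure:
    """Copy of ``structure`` with per-residue importance in the B-factor.

    Intended for export as a painted PDB viewable in any molecular viewer
    (the study-style 0–15 % colour scale is a viewer setting).
    """
    out = structure.copy()
    out.bfactor = np.zeros(out.n_atoms)
    for (chain, resnum), pct in importance.per_residue.items():
        idx = out.residue_atom_indices(chain, resnum)
        out.bfactor[idx] = pct
    return out
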