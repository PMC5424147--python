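"""Temporally concatenated group spatial ICA with stability selection.

Workflow: subject/task runs are stacked in time and reduced with a single
group PCA; spatial ICA (FastICA, logcosh contrast) is repeated from many
random initializations; the pooled components are clustered by absolute
spatial correlation and each cluster's centrotype is returned together with
a stability index Iq (mean intra-cluster minus mean extra-cluster
similarity).  Subject- and task-specific time-courses and maps are obtained
by back-reconstruction in which the subject maps average to the group map.

Map sign convention: each group map is flipped so its skewness is positive,
making results deterministic up to component order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA

from .preprocess import GridError


class InstabilityError(RuntimeError):
    pass


class UnknownSubjectError(KeyError):
    pass


@dataclass
class ReducedData:
    """Group-PCA-reduced concatenated data plus stacking bookkeeping."""
    X: np.ndarray                 # n_keep x n_voxels (reduced data)
    G: np.ndarray                 # total_volumes x n_keep (basis loadings)
    blocks: list                  # of (key, start, stop) row ranges in G
    grid_shape: tuple
    voxel_mean: np.ndarray        # pooled temporal mean per voxel
    explained_variance_ratio: np.ndarray

    def block_rows(self, key):
        for k, start, stop in self.blocks:
            if k == key:
                return start, stop
        raise UnknownSubjectError(f"{key!r} was not part of the concatenation")


def _flatten(image: np.ndarray) -> np.ndarray:
    """4D image -> (time x voxels)."""
    return image.reshape(-1, image.shape[3]).T


def concatenate_and_reduce(images: list, n_keep: int) -> ReducedData:
    """Stack runs in time (in the given order) and reduce by group PCA.

    ``images`` is a list of (key, 4D array); all runs must share the voxel
    grid.  Returns the reduced data X (n_keep x voxels), the basis G such
    that the centered stacked data ~= G @ X, and the stacking order.
    """
    if not images:
        raise ValueError("no images supplied")
    grid = images[0][1].shape[:3]
    mats, blocks, start = [], [], 0
    for key, img in images:
        if img.shape[:3] != grid:
            raise GridError(f"grid mismatch for {key!r}: "
                            f"{img.shape[:3]} != {grid}")
        m = _flatten(np.asarray(img, dtype=float))
        blocks.append((key, start, start + m.shape[0]))
        start += m.shape[0]
        mats.append(m)
    Y = np.vstack(mats)
    if n_keep > Y.shape[0]:
        raise ValueError("n_keep exceeds total volume count")
    voxel_mean = Y.mean(axis=0)
    Yc = Y - voxel_mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    G = U[:, :n_keep] * s[:n_keep]
    X = Vt[:n_keep]
    return ReducedData(X=X, G=G, blocks=blocks, grid_shape=grid,
                       voxel_mean=voxel_mean,
                       explained_variance_ratio=evr[:n_keep])


def _fix_signs(maps: np.ndarray) -> np.ndarray:
    signs = np.sign(skew(maps, axis=1))
    signs[signs == 0] = 1.0
    return maps * signs[:, None]


def _unit_variance(maps: np.ndarray) -> np.ndarray:
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return maps / sd


def spatial_similarity(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation matrix between two sets of maps."""
    A = maps_a - maps_a.mean(axis=1, keepdims=True)
    B = maps_b - maps_b.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return np.abs(A @ B.T)


@dataclass
class GroupDecomposition:
    maps: np.ndarray              # k x voxels, unit variance, skew-positive
    mixing: np.ndarray            # reduced-dim x k
    stability_iq: np.ndarray      # k
    n_repeats_used: int
    seed: int

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


def run_stable_ica(reduced: ReducedData, k: int, n_repeats: int = 16,
                   seed: int = 0, max_iter: int = 500,
                   tol: float = 1e-4) -> GroupDecomposition:
    """Spatial ICA with stability (ICASSO-style) selection.

    FastICA (logcosh) is run ``n_repeats`` times from different random
    initializations on the reduced data; all estimated spatial maps are
    pooled and clustered (average-linkage agglomerative on 1 − |spatial
    correlation|) into ``k`` clusters.  Each cluster is summarized by its
    centrotype (the member with the largest within-cluster similarity sum)
    and the stability index Iq = mean intra-cluster − mean extra-cluster
    similarity.  Non-convergent repeats are dropped with a warning; if more
    than half drop, an InstabilityError is raised.
    """
    if k > reduced.X.shape[0]:
        raise ValueError("k exceeds reduced dimensionality")
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    rng = np.random.default_rng(seed)
    all_maps, kept = [], 0
    for rep in range(n_repeats):
        ica = FastICA(n_components=k, fun="logcosh", max_iter=max_iter,
                      tol=tol, whiten="unit-variance",
                      random_state=int(rng.integers(0, 2 ** 31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = ica.fit_transform(reduced.X.T).T       # k x voxels
        if ica.n_iter_ >= max_iter:
            warnings.warn(f"ICA repeat {rep} did not converge; dropped")
            continue
        all_maps.append(_unit_variance(S))
        kept += 1
    if kept <= n_repeats / 2:
        raise InstabilityError(
            f"only {kept}/{n_repeats} ICA repeats converged")
    pooled = np.vstack(all_maps)                       # (kept*k) x voxels
    sim = spatial_similarity(pooled, pooled)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    labels = fcluster(linkage(dist, method="average"), t=k,
                      criterion="maxclust")
    centro_idx, iqs = [], []
    for lab in range(1, k + 1):
        members = np.where(labels == lab)[0]
        sub = sim[np.ix_(members, members)]
        within_sums = sub.sum(axis=1)
        centro = members[np.argmax(within_sums)]
        if len(members) > 1:
            intra = (sub.sum() - len(members)) / \
                (len(members) * (len(members) - 1))
        else:
            intra = 1.0
        outside = np.setdiff1d(np.arange(pooled.shape[0]), members)
        extra = sim[np.ix_(members, outside)].mean() if len(outside) else 0.0
        centro_idx.append(centro)
        iqs.append(intra - extra)
    maps = _fix_signs(_unit_variance(pooled[centro_idx]))
    # mixing: regression of the reduced data on the selected maps
    Mc = maps - maps.mean(axis=1, keepdims=True)
    A = reduced.X @ Mc.T @ np.linalg.inv(Mc @ Mc.T)
    return GroupDecomposition(maps=maps, mixing=A,
                              stability_iq=np.asarray(iqs),
                              n_repeats_used=kept, seed=seed)


@dataclass
class SubjectComponentData:
    """Back-reconstructed subject/task time-courses and spatial maps."""
    timecourses: dict             # key -> (n_volumes x k)
    maps: dict                    # key -> (k x voxels)
    keys: list


def back_reconstruct_gica3(decomp: GroupDecomposition, reduced: ReducedData,
                           images: dict) -> SubjectComponentData:
    """Back-reconstruct subject-specific component data.

    Time-courses are the rows of G @ A belonging to each run; subject maps
    are the least-squares solution of the run's (pooled-mean-centered) data
    on its time-courses, so that on data exactly spanned by the group model
    the subject maps average to the group map.
    """
    R = reduced.G @ decomp.mixing            # total_volumes x k
    tcs, maps = {}, {}
    for key, start, stop in reduced.blocks:
        if key not in images:
            raise UnknownSubjectError(f"no image supplied for {key!r}")
        tc = R[start:stop]
        Y = _flatten(np.asarray(images[key], dtype=float)) - \
            reduced.voxel_mean
        S_i, *_ = np.linalg.lstsq(tc, Y, rcond=None)
        tcs[key] = tc
        maps[key] = S_i
    return SubjectComponentData(timecourses=tcs, maps=maps,
                                keys=[b[0] for b in reduced.blocks])


def match_components(maps_a: np.ndarray, maps_b: np.ndarray):
    """One-to-one match of two map sets by absolute spatial correlation
    (Hungarian assignment).  Returns (rows, cols, matched |r| values)."""
    sim = spatial_similarity(maps_a, maps_b)
    rows, cols = linear_sum_assignment(-sim)
    return rows, cols, sim[rows, cols]


def select_dimensionality(per_task_images: dict, candidate_ks,
                          n_repeats: int = 8, seed: int = 0) -> tuple:
    """Choose the ICA order maximizing single-task/joint-task convergence.

    For each candidate k, an ICA is run on each task alone and on the joint
    (all-task) concatenation; joint components are matched one-to-one to
    each single-task set by absolute spatial correlation and the
    convergence score is the mean matched |r| averaged over tasks.  Returns
    (k_star, {k: convergence}); ties break to the smaller k.
    """
    ks = sorted(candidate_ks)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate orders")
    joint_images = [pair for task in per_task_images
                    for pair in per_task_images[task]]
    scores = {}
    for k in ks:
        try:
            joint_red = concatenate_and_reduce(joint_images, k)
            joint = run_stable_ica(joint_red, k, n_repeats, seed)
            task_scores = []
            for task, imgs in per_task_images.items():
                red = concatenate_and_reduce(imgs, k)
                single = run_stable_ica(red, k, n_repeats, seed + 1)
                _, _, matched = match_components(joint.maps, single.maps)
                task_scores.append(float(matched.mean()))
            scores[k] = float(np.mean(task_scores))
        except (InstabilityError, ValueError) as exc:   # pragma: no cover
            warnings.warn(f"order k={k} skipped: {exc}")
    if not scores:
        raise InstabilityError("all candidate orders failed")
    best = max(scores.values())
    k_star = min(k for k, v in scores.items() if v >= best - 1e-12)
    return k_star, scores


def save_decomposition(decomp: GroupDecomposition, reduced: ReducedData,
                       outdir) -> None:
    """Persist group maps as NIfTI plus a JSON manifest."""
    import pathlib

    import nibabel as nib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(decomp.maps):
        img = nib.Nifti1Image(
            m.reshape(reduced.grid_shape).astype(np.float32), np.eye(4))
        nib.save(img, str(out / f"component_{i:02d}.nii"))
    manifest = {
        "n_components": decomp.n_components,
        "stability_iq": decomp.stability_iq.tolist(),
        "n_repeats_used": decomp.n_repeats_used,
        "seed": decomp.seed,
        "blocks": [[str(k), int(a), int(b)] for k, a, b in reduced.blocks],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
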