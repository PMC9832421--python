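"""Conformational landscapes: tables of coefficient sets, clustering into
representative states, and 2D embeddings.

Each row of a :class:`LandscapeTable` is one conformation — estimated from
a particle, a map, or a model — flattened to a 3K coefficient vector.
Distances are plain Euclidean on that vector; since the basis is
orthonormal on the unit ball this is (up to the vector mixing) an L2
distance between deformation fields.  Cluster representatives are medoids
(the realized conformation nearest each centroid), so a synthesized state
always corresponds to an actually observed conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .basis import BasisSpec, enumerate_indices
from .field import (
    AtomicModel,
    CoefficientSet,
    VolumeGrid,
    deformation_magnitude,
    negate,
    warp_model,
    warp_volume,
)

__all__ = [
    "LandscapeTable",
    "assemble",
    "cluster_representatives",
    "cluster_labels",
    "embed_2d",
    "synthesize_state",
]

KINDS = ("particle", "map", "model")


@dataclass
class LandscapeTable:
    """Rows of flattened coefficient vectors with provenance and scores."""

    spec: BasisSpec
    scale_radius: float
    ids: list
    kinds: list
    vectors: np.ndarray      # (nrows, 3K), direction-major flat order
    magnitudes: np.ndarray   # Angstrom
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.ids) == 0:
            self.vectors = self.vectors.reshape(0, 3 * self.spec.size)
        if self.vectors.shape[1] != 3 * self.spec.size:
            raise ValueError("vector length does not match the basis spec")
        if np.any(np.asarray(self.magnitudes) < 0):
            raise ValueError("deformation magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def coefficient_set(self, i: int) -> CoefficientSet:
        return CoefficientSet.from_flat(self.spec, self.vectors[i],
                                        self.scale_radius)

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {}
        cols["id"] = self.ids
        cols["kind"] = self.kinds
        cols["score"] = self.scores
        cols["magnitude_A"] = self.magnitudes
        names = [
            f"a{l}_{n}_{m}_{ax}"
            for ax in "xyz"
            for (l, n, m) in enumerate_indices(self.spec)
        ]
        for j, name in enumerate(names):
            cols[name] = self.vectors[:, j]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# zflex-landscape v1 N={self.spec.N} L={self.spec.L} "
                     f"p={self.spec.p} scale_radius={self.scale_radius}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "LandscapeTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# zflex-landscape v1"):
                raise ValueError(f"{path}: not a zflex landscape table")
            fields = dict(tok.split("=") for tok in header.split()[3:])
            spec = BasisSpec(int(fields["N"]), int(fields["L"]),
                             float(fields["p"]))
            df = pd.read_csv(fh, float_precision="round_trip")
        vec_cols = [c for c in df.columns if c.startswith("a")]
        if len(vec_cols) != 3 * spec.size:
            raise ValueError("coefficient column count mismatch")
        return cls(
            spec=spec,
            scale_radius=float(fields["scale_radius"]),
            ids=df["id"].tolist(),
            kinds=df["kind"].tolist(),
            vectors=df[vec_cols].to_numpy(),
            magnitudes=df["magnitude_A"].to_numpy(),
            scores=df["score"].to_numpy(),
        )


def assemble(items, mask: VolumeGrid | None = None) -> LandscapeTable:
    """Build a landscape table from (id, kind, CoefficientSet, score) items.

    All coefficient sets must share one BasisSpec and scale_radius (use
    :func:`zflex.field.rescale_coefficients` first if they do not).
    Deformation magnitudes are computed over ``mask`` when given.
    """
    items = list(items)
    if not items:
        return LandscapeTable(BasisSpec(3, 2), 1.0, [], [],
                              np.zeros((0, 39)), np.zeros(0), np.zeros(0))
    specs = {it[2].spec for it in items}
    radii = {it[2].scale_radius for it in items}
    if len(specs) > 1 or len(radii) > 1:
        raise ValueError(
            "mixed basis specs or scale radii; rescale_coefficients first"
        )
    for _id, kind, _c, _s in items:
        if kind not in KINDS:
            raise ValueError(f"unknown row kind {kind!r}")
    spec = items[0][2].spec
    return LandscapeTable(
        spec=spec,
        scale_radius=items[0][2].scale_radius,
        ids=[it[0] for it in items],
        kinds=[it[1] for it in items],
        vectors=np.array([it[2].flatten() for it in items]),
        magnitudes=np.array([deformation_magnitude(it[2], mask) for it in items]),
        scores=np.array([float(it[3]) for it in items]),
    )


def cluster_labels(t: LandscapeTable, n: int, seed: int = 0):
    """KMeans labels and medoid row indices on the raw coefficient vectors."""
    if n < 1 or n > len(t):
        raise ValueError(f"need 1 <= n <= {len(t)} clusters, got {n}")
    km = KMeans(n_clusters=n, n_init=10, random_state=seed)
    labels = km.fit_predict(t.vectors)
    medoids = []
    for k in range(n):
        rows = np.flatnonzero(labels == k)
        dist = np.linalg.norm(t.vectors[rows] - km.cluster_centers_[k], axis=1)
        medoids.append(int(rows[np.argmin(dist)]))
    return labels, medoids


def cluster_representatives(t: LandscapeTable, n: int, seed: int = 0):
    """Representative coefficient set of each KMeans cluster.

    The representative is the medoid — the member row nearest its cluster
    centroid — so every representative is a realized conformation.
    Deterministic for a fixed seed and row set.
    """
    _labels, medoids = cluster_labels(t, n, seed)
    return [t.coefficient_set(i) for i in medoids]


def embed_2d(t: LandscapeTable, method: str = "pca", seed: int = 0) -> np.ndarray:
    """2D embedding of the coefficient vectors (one row per table row).

    ``pca`` is exact principal components (deterministic up to a fixed
    sign convention); ``umap`` delegates to umap-learn with the given
    random_state and is only as reproducible as that library makes it.
    """
    if len(t) < 3:
        raise ValueError("need at least 3 rows to embed")
    if method == "pca":
        p = PCA(n_components=2, svd_solver="full")
        Y = p.fit_transform(t.vectors)
        # fix sign: largest-|loading| component of each axis positive
        for j in range(Y.shape[1]):
            k = np.argmax(np.abs(p.components_[j]))
            if p.components_[j, k] < 0:
                Y[:, j] *= -1
        return Y
    if method == "umap":
        import umap

        return umap.UMAP(n_components=2, random_state=seed).fit_transform(
            t.vectors
        )
    raise ValueError(f"unknown embedding method {method!r}")


def synthesize_state(c: CoefficientSet, reference: VolumeGrid,
                     model: AtomicModel | None = None):
    """Realize the conformation ``c`` as a density map (and optional model).

    The map is the reference gather-warped with ``c`` (same grid and
    sampling as the reference, so no resolution is lost); atoms move with
    the density, i.e. with the negated field (see :mod:`zflex.field` on
    the sign convention).
    """
    if reference.default_scale_radius != c.scale_radius:
        raise ValueError(
            f"coefficient scale_radius {c.scale_radius} does not match the "
            f"reference's inscribed radius {reference.default_scale_radius}"
        )
    vol = warp_volume(reference, c)
    mdl = warp_model(model, negate(c)) if model is not None else None
    return vol, mdl
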