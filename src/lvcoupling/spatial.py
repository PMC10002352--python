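"""Spatial weights and permutation-tested Moran statistics on rank codings.

Weights come from queen contiguity (polygons sharing at least one boundary
point), from explicit edge lists, or from economic-region block membership
(weight 1 between any two entities of the same region).  Entities with no
contiguity neighbour (an island province, say) can be linked explicitly via
``extra_links``.

Global Moran's I is the standard cross-product statistic

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,

with z the deviations from the mean and S0 the sum of weights; its
expectation under the exchangeable null is -1/(n-1).  The local (LISA)
decomposition is I_i = (z_i / m2) * sum_j w_ij z_j with m2 = sum z^2 / n.
Inference is Monte-Carlo: full random relabelings for the global statistic,
conditional permutation (the focal value held fixed, the rest shuffled over
the remaining sites) for the local ones.  Pseudo p-values follow the
plus-one rule, one-sided in the direction of the observed deviation from
the null expectation, ties counting as extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import (
    CodingError,
    ConstantValuesError,
    EmptyWeightsError,
    GeometryError,
    IsolateError,
    LabelError,
)

logger = logging.getLogger(__name__)

Scheme = Literal["binary", "row_standardized"]
Category = Literal["high_high", "low_low", "low_high", "high_low",
                   "not_significant"]

#: Default ordinal coding of the six rank letters (best = largest).
DEFAULT_RANK_CODING: dict[str, float] = {
    "S": 6, "A": 5, "B": 4, "C": 3, "D": 2, "E": 1,
}


@dataclass(frozen=True)
class SpatialWeights:
    """Labeled weight matrix with zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    scheme: Scheme
    provenance: str = "custom"  # "queen" | "block" | "custom"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise LabelError("need at least two entities")
        if self.matrix.shape != (n, n):
            raise LabelError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if np.abs(np.diag(self.matrix)).max() > 0:
            raise GeometryError("weight matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, keep: Sequence[str]) -> "SpatialWeights":
        """Restrict to a label subset, rebuilding the scheme on the subgraph."""
        idx = [self.labels.index(k) for k in keep]
        sub = self.matrix[np.ix_(idx, idx)]
        binary = (sub > 0).astype(float)
        return SpatialWeights(
            labels=tuple(keep),
            matrix=_apply_scheme(binary, self.scheme),
            scheme=self.scheme,
            provenance=self.provenance,
        )


def _apply_scheme(binary: np.ndarray, scheme: Scheme) -> np.ndarray:
    if scheme == "binary":
        return binary
    if scheme == "row_standardized":
        rowsum = binary.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rowsum > 0, binary / rowsum, 0.0)
        return out
    raise ValueError(f"unknown scheme {scheme!r}")


def queen_contiguity(polygons: Mapping[str, object]) -> set[tuple[str, str]]:
    """Queen-adjacency edges: polygons sharing at least one boundary point.

    ``polygons`` maps entity label -> shapely geometry.  Corner contacts
    count (that is the queen, as opposed to rook, criterion).
    """
    from shapely.validation import explain_validity

    labels = sorted(polygons)
    if not labels:
        raise GeometryError("empty geometry collection")
    for lbl in labels:
        geom = polygons[lbl]
        if geom is None or getattr(geom, "is_empty", True):
            raise GeometryError(f"{lbl}: empty geometry")
        if not geom.is_valid:
            raise GeometryError(f"{lbl}: invalid geometry "
                                f"({explain_validity(geom)})")
    edges: set[tuple[str, str]] = set()
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if polygons[a].intersects(polygons[b]):
                edges.add((a, b))
    return edges


def load_geojson_polygons(path: str, name_property: str = "name"
                          ) -> dict[str, object]:
    """Read a GeoJSON FeatureCollection into label -> shapely geometry."""
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, object] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        if name_property not in props:
            raise LabelError(f"feature missing property {name_property!r}")
        out[str(props[name_property])] = shape(feat["geometry"])
    return out


def build_weights(edges: Iterable[tuple[str, str]], labels: Sequence[str],
                  extra_links: Iterable[tuple[str, str]] = (),
                  scheme: Scheme = "row_standardized",
                  strict: bool = False,
                  provenance: str = "queen") -> SpatialWeights:
    """Binary symmetric weights from an edge set, plus explicit extra links.

    ``extra_links`` both adds the edges and exempts their endpoints from the
    isolate check, the mechanism used to attach an island province to its
    nearest mainland neighbour.  Isolates that remain are warned about, or
    rejected in strict mode.
    """
    labels = tuple(labels)
    index = {lbl: i for i, lbl in enumerate(labels)}
    extra = [tuple(e) for e in extra_links]
    mat = np.zeros((len(labels), len(labels)))
    for a, b in list(edges) + extra:
        if a not in index or b not in index:
            unknown = a if a not in index else b
            raise LabelError(f"edge endpoint {unknown!r} not in labels")
        if a == b:
            continue
        mat[index[a], index[b]] = 1.0
        mat[index[b], index[a]] = 1.0
    exempt = {x for e in extra for x in e}
    isolates = [lbl for lbl in labels
                if mat[index[lbl]].sum() == 0 and lbl not in exempt]
    if isolates:
        msg = f"isolated entities with no exemption: {isolates}"
        if strict:
            raise IsolateError(msg)
        logger.warning(msg)
    return SpatialWeights(labels=labels, matrix=_apply_scheme(mat, scheme),
                          scheme=scheme, provenance=provenance)


def region_block_weights(region_of: Mapping[str, str], labels: Sequence[str],
                         scheme: Scheme = "row_standardized",
                         union_edges: Iterable[tuple[str, str]] = ()
                         ) -> SpatialWeights:
    """Block weights: 1 between distinct entities of the same region.

    ``union_edges`` optionally unions a contiguity edge set into the blocks
    (neighbours *or* same region), for the reading of regional adjacency
    that keeps physical neighbours connected across region borders.
    Singleton regions produce isolates, which are flagged.
    """
    labels = tuple(labels)
    missing = [lbl for lbl in labels if lbl not in region_of]
    if missing:
        raise LabelError(f"entities without a region: {missing}")
    index = {lbl: i for i, lbl in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if region_of[a] == region_of[labels[j]]:
                mat[i, j] = mat[j, i] = 1.0
    for a, b in union_edges:
        if a not in index or b not in index:
            raise LabelError(f"edge endpoint not in labels: {(a, b)}")
        if a != b:
            mat[index[a], index[b]] = mat[index[b], index[a]] = 1.0
    isolates = [lbl for lbl in labels if mat[index[lbl]].sum() == 0]
    if isolates:
        logger.warning("singleton-region isolates: %s", isolates)
    return SpatialWeights(labels=labels, matrix=_apply_scheme(mat, scheme),
                          scheme=scheme, provenance="block")


def encode_ranks(ranks: Sequence[str],
                 coding: Mapping[str, float] | None = None) -> np.ndarray:
    """Map rank letters to a numeric vector (default S=6 ... E=1).

    Moran's I is invariant under affine transformations of the values, so
    any equispaced monotone coding yields the same statistic.
    """
    coding = dict(coding) if coding is not None else DEFAULT_RANK_CODING
    try:
        return np.array([coding[r] for r in ranks], dtype=float)
    except KeyError as exc:
        raise CodingError(f"rank letter {exc.args[0]!r} has no coding") from exc


def _deviations(values: np.ndarray) -> np.ndarray:
    z = values - values.mean()
    if np.allclose(z, 0.0):
        raise ConstantValuesError("constant attribute vector: I undefined")
    return z


def global_moran(values: Sequence[float], w: SpatialWeights) -> float:
    """Global Moran's I of an attribute vector under a weight matrix."""
    x = np.asarray(values, dtype=float)
    if len(x) != w.n:
        raise LabelError(f"{len(x)} values for {w.n} entities")
    s0 = w.matrix.sum()
    if s0 == 0:
        raise EmptyWeightsError("all weights are zero")
    z = _deviations(x)
    return float(w.n / s0 * (z @ w.matrix @ z) / (z @ z))


def expected_moran(n: int) -> float:
    """Null expectation of global Moran's I: -1/(n-1)."""
    return -1.0 / (n - 1)


@dataclass(frozen=True)
class MoranGlobalResult:
    """Global Moran's I with Monte-Carlo permutation inference."""

    observed_i: float
    expected_i: float
    pseudo_p: float
    n_permutations: int
    seed: int
    n: int

    @property
    def p_two_sided(self) -> float:
        """Directional pseudo-p folded to a calibrated two-sided level."""
        return min(1.0, 2.0 * self.pseudo_p)

    def significant(self, alpha: float = 0.1) -> bool:
        """Size-calibrated decision: rejects a true exchangeable null at
        rate ~= alpha (the directional pseudo-p alone would double that)."""
        return self.p_two_sided < alpha


@dataclass(frozen=True)
class LisaResult:
    """Per-entity local Moran statistics with conditional-permutation p."""

    labels: tuple[str, ...]
    local_i: np.ndarray
    pseudo_p: np.ndarray
    seed: int
    n_permutations: int
    categories: tuple[Category, ...] = field(default=())


def permutation_test_global(values: Sequence[float], w: SpatialWeights,
                            n_perm: int = 999, seed: int = 0
                            ) -> MoranGlobalResult:
    """Monte-Carlo permutation test for global Moran's I.

    Full random relabelings of the attribute vector; the pseudo p-value is
    (1 + #{permuted I at least as extreme as observed, in the observed
    direction relative to E[I]}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(values, dtype=float)
    obs = global_moran(x, w)
    e_i = expected_moran(w.n)
    rng = np.random.default_rng(seed)
    s0 = w.matrix.sum()
    z = x - x.mean()
    denom = z @ z
    sims = np.empty(n_perm)
    for k in range(n_perm):
        zp = rng.permutation(z)
        sims[k] = w.n / s0 * (zp @ w.matrix @ zp) / denom
    if obs >= e_i:
        extreme = int((sims >= obs).sum())
    else:
        extreme = int((sims <= obs).sum())
    p = (1 + extreme) / (1 + n_perm)
    return MoranGlobalResult(observed_i=obs, expected_i=e_i, pseudo_p=p,
                             n_permutations=n_perm, seed=seed, n=w.n)


def local_moran(values: Sequence[float], w: SpatialWeights,
                n_perm: int = 999, seed: int = 0) -> LisaResult:
    """Local Moran's I (LISA) with conditional-permutation p-values.

    For each site the focal value is held fixed and the remaining n-1
    values are randomly reassigned to the other sites; only the weighted
    neighbour sum matters, so each draw samples the neighbour values
    directly.  Isolates get I_i = 0 and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(values, dtype=float)
    if len(x) != w.n:
        raise LabelError(f"{len(x)} values for {w.n} entities")
    z = _deviations(x)
    n = w.n
    m2 = (z @ z) / n
    lag = w.matrix @ z
    li = z / m2 * lag
    rng = np.random.default_rng(seed)
    pseudo = np.ones(n)
    for i in range(n):
        wi = w.matrix[i]
        nbr = np.flatnonzero(wi)
        if nbr.size == 0:
            li[i] = 0.0
            pseudo[i] = 1.0
            continue
        others = np.delete(z, i)
        w_row = wi[nbr]
        # E[I_i] under conditional permutation: lag averages the other
        # values, whose mean is -z_i/(n-1) because the z sum to zero.
        e_li = z[i] / m2 * wi.sum() * (-z[i] / (n - 1))
        sims = np.empty(n_perm)
        for k in range(n_perm):
            draw = rng.choice(others, size=nbr.size, replace=False)
            sims[k] = z[i] / m2 * (w_row @ draw)
        if li[i] >= e_li:
            extreme = int((sims >= li[i]).sum())
        else:
            extreme = int((sims <= li[i]).sum())
        pseudo[i] = (1 + extreme) / (1 + n_perm)
    return LisaResult(labels=w.labels, local_i=li, pseudo_p=pseudo,
                      seed=seed, n_permutations=n_perm)


def classify_clusters(values: Sequence[float], w: SpatialWeights,
                      lisa: LisaResult, alpha: float = 0.1
                      ) -> tuple[Category, ...]:
    """LISA cluster categories at significance level ``alpha``.

    Significant sites are labeled by the sign of their own deviation and of
    their spatial lag: high-high, low-low, low-high, high-low; everything
    else is not significant.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    lag = w.matrix @ z
    cats: list[Category] = []
    for i in range(w.n):
        if lisa.pseudo_p[i] >= alpha or w.matrix[i].sum() == 0:
            cats.append("not_significant")
        elif z[i] >= 0:
            cats.append("high_high" if lag[i] >= 0 else "high_low")
        else:
            cats.append("low_high" if lag[i] >= 0 else "low_low")
    return tuple(cats)
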