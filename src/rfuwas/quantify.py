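"""Repertoire quantification: CDR3 sequences -> RFU abundance vectors.

A repertoire functional unit (RFU) is a cluster of TCR CDR3 sequences with
similar embedding coordinates.  A repertoire is quantified by assigning each
unique CDR3 to its nearest centroid (Euclidean distance, lowest-index
tie-break) and counting clonotypes per RFU; the resulting abundance vector
is the molecular trait every downstream stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import AtchleyEncoder


@dataclass
class Repertoire:
    """One individual's CDR3 clonotypes with clone counts.

    ``clones`` maps CDR3 amino-acid string -> positive clone count; the key
    set is the unique-clonotype set, so ``n_unique`` is just its size.
    """

    individual_id: str
    clones: dict[str, int]
    time_point: str | None = None

    def __post_init__(self):
        for seq, count in self.clones.items():
            if count < 1:
                raise ValueError(f"clone count for {seq!r} must be >= 1, got {count}")

    @property
    def n_unique(self) -> int:
        return len(self.clones)

    @property
    def total_count(self) -> int:
        return sum(self.clones.values())


@dataclass
class RFUCentroids:
    """Centroid coordinates of the RFU clusters in embedding space."""

    matrix: np.ndarray  # (n_rfus, d)
    rfu_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("centroid matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("centroid coordinates must be finite")
        if not self.rfu_ids:
            self.rfu_ids = [f"RFU{i}" for i in range(self.matrix.shape[0])]
        if len(self.rfu_ids) != self.matrix.shape[0]:
            raise ValueError("rfu_ids length does not match centroid rows")
        if len(set(self.rfu_ids)) != len(self.rfu_ids):
            raise ValueError("rfu_ids must be unique")

    @property
    def n_rfus(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AbundanceMatrix:
    """Individuals x RFUs abundance values with a processing-stage tag.

    ``stage`` is one of ``raw`` (clonotype counts), ``quantile``,
    ``inverse_normal`` or ``residual``; at the raw stage each row sums to
    the number of clonotypes assigned for that individual.
    """

    data: pd.DataFrame  # index: individual ids, columns: rfu ids
    stage: str = "raw"

    _STAGES = ("raw", "quantile", "inverse_normal", "residual")

    def __post_init__(self):
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def individual_ids(self) -> list:
        return list(self.data.index)

    @property
    def rfu_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


class RFUAssigner(BaseEstimator, TransformerMixin):
    """Nearest-centroid quantifier for CDR3 repertoires.

    Parameters
    ----------
    encoder : object, optional
        CDR3 encoder with ``encode``/``encode_many``; default
        :class:`~rfuwas.encoding.AtchleyEncoder`.
    weighted : bool, default False
        If True, abundance is the sum of clone counts per RFU
        (read-weighted); default counts unique clonotypes, matching the
        emphasis on unique CDR3 beta chains per repertoire.
    """

    def __init__(self, encoder=None, weighted: bool = False):
        self.encoder = encoder
        self.weighted = weighted

    def fit(self, centroids: RFUCentroids, y=None):
        if centroids.n_rfus == 0:
            raise ValueError("centroid set is empty")
        self.centroids_ = centroids
        self.encoder_ = self.encoder if self.encoder is not None else AtchleyEncoder()
        return self

    def assign_indices(self, sequences) -> np.ndarray:
        """Map each CDR3 string to the index of its nearest centroid.

        Ties are broken toward the lowest centroid index (argmin over the
        squared Euclidean distances returns the first minimum).
        """
        if len(sequences) == 0:
            return np.empty(0, dtype=int)
        emb = self.encoder_.encode_many(sequences)
        C = self.centroids_.matrix
        # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2; the ||x||^2 term is
        # constant per row and dropped before the argmin.
        d2 = (C * C).sum(axis=1)[None, :] - 2.0 * emb @ C.T
        return np.argmin(d2, axis=1)

    def transform_one(self, repertoire: Repertoire) -> np.ndarray:
        """Quantify one repertoire into a raw abundance row."""
        row = np.zeros(self.centroids_.n_rfus)
        if repertoire.n_unique == 0:
            warnings.warn(
                f"empty repertoire for {repertoire.individual_id}; all-zero row",
                stacklevel=2,
            )
            return row
        seqs = list(repertoire.clones)
        idx = self.assign_indices(seqs)
        if self.weighted:
            w = np.array([repertoire.clones[s] for s in seqs], dtype=float)
            np.add.at(row, idx, w)
        else:
            np.add.at(row, idx, 1.0)
        return row

    def transform(self, repertoires) -> AbundanceMatrix:
        """Quantify a list of repertoires into a raw AbundanceMatrix."""
        rows = [self.transform_one(r) for r in repertoires]
        data = pd.DataFrame(
            np.array(rows).reshape(len(rows), -1) if rows else np.empty((0, self.centroids_.n_rfus)),
            index=[r.individual_id for r in repertoires],
            columns=self.centroids_.rfu_ids,
        )
        return AbundanceMatrix(data, stage="raw")


def assign_rfus(
    repertoire: Repertoire,
    centroids: RFUCentroids,
    encoder=None,
    weighted: bool = False,
) -> np.ndarray:
    """Raw RFU abundance row for one repertoire (thin estimator wrapper)."""
    return RFUAssigner(encoder=encoder, weighted=weighted).fit(centroids).transform_one(repertoire)


def aggregate_timepoints(repertoires: list[Repertoire]) -> Repertoire:
    """Pool one individual's repertoires across time points.

    Counts of identical CDR3 strings are summed; the unique-clonotype set of
    the result is the union over time points.
    """
    if not repertoires:
        raise ValueError("no repertoires to aggregate")
    ids = {r.individual_id for r in repertoires}
    if len(ids) != 1:
        raise ValueError(f"mixed individual_ids in aggregation: {sorted(ids)}")
    merged: dict[str, int] = {}
    for r in repertoires:
        for seq, count in r.clones.items():
            merged[seq] = merged.get(seq, 0) + count
    return Repertoire(individual_id=repertoires[0].individual_id, clones=merged)


def select_top_clones(repertoire: Repertoire, n: int) -> Repertoire:
    """Keep the ``n`` clonotypes with the largest clone counts.

    Ties at the retention boundary are broken by lexicographic CDR3 order;
    repertoires with at most ``n`` clones are returned unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if repertoire.n_unique <= n:
        return repertoire
    ranked = sorted(repertoire.clones.items(), key=lambda kv: (-kv[1], kv[0]))
    return Repertoire(
        individual_id=repertoire.individual_id,
        clones=dict(ranked[:n]),
        time_point=repertoire.time_point,
    )
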