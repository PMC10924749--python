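"""Feature database construction and z-score-ranked structure search.

A database is the feature matrix of every structure in a collection,
built with one fixed SIFT parameter set. A search compares the query
against every entry, standardizes the match counts and match scores
across the whole comparison population (z-scores with the population
standard deviation), and ranks hits by the summed z-score
z_sum = z_m + z_s. Raw (m, s) values are not comparable across targets
of different sizes; standardizing within the search population is what
makes the ranking scale-free.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AdamsError,
    EmptyDatabaseError,
    InvalidInputError,
    ParameterError,
)
from .features import (
    LOW_FEATURE_FLOOR,
    FeatureMatrix,
    Keypoint,
    SiftParams,
    extract_features,
)
from .matching import MatchResult, match_features
from .structure_io import (
    CalphaTrace,
    compute_distance_matrix,
    load_calpha_trace,
    normalize_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureDatabase",
    "SearchReport",
    "Hit",
    "build_database",
    "zscore",
    "search",
    "TSV_HEADER",
]

TSV_HEADER = (
    "query_id\ttarget_id\tn_query_features\tn_target_features"
    "\tm\ts\tz_m\tz_s\tz_sum\trank"
)


def zscore(values) -> np.ndarray:
    """Standardize a population of reals: (x - mean) / std.

    Uses the population (not sample) standard deviation. A zero-variance
    population — including a single value — standardizes to all zeros,
    keeping the function total.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidInputError("cannot standardize an empty population")
    sd = values.std()
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass
class FeatureDatabase:
    """Id-indexed feature matrices plus the build manifest.

    All entries are built with one SIFT parameter set; mixing parameter
    sets within a database is a build error. ``manifest`` preserves build
    order (which fixes the reduction order of every search) and records
    files that were skipped.
    """

    params: SiftParams = field(default_factory=SiftParams)
    entries: dict[str, FeatureMatrix] = field(default_factory=dict)
    manifest: list[dict] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)

    def add(self, fm: FeatureMatrix, source: str = "") -> None:
        if fm.id in self.entries:
            raise InvalidInputError(f"duplicate database id: {fm.id!r}")
        self.entries[fm.id] = fm
        self.manifest.append(
            {"id": fm.id, "n_features": fm.n_features, "source": source}
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self.entries

    # -- archive format -------------------------------------------------
    # A zip of .npy members written with fixed timestamps, so rebuilding
    # from identical inputs produces a byte-identical file. Descriptors
    # are stored as float32 (unit norm is preserved well within 1e-6);
    # keypoints as (n, 5) float64 [row, col, scale, orientation, response].

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        meta = {
            "format_version": 1,
            "params": self.params.to_dict(),
            "manifest": self.manifest,
            "excluded": self.excluded,
        }
        arrays["meta.json"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
        for i, entry in enumerate(self.manifest):
            fm = self.entries[entry["id"]]
            arrays[f"desc_{i}"] = fm.descriptors.astype(np.float32)
            arrays[f"kp_{i}"] = np.array(
                [
                    [k.row, k.col, k.scale, k.orientation, k.response]
                    for k in fm.keypoints
                ],
                dtype=np.float64,
            ).reshape(fm.n_features, 5)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in sorted(arrays):
                buf = io.BytesIO()
                np.lib.format.write_array(
                    buf, np.ascontiguousarray(arrays[name]),
                    allow_pickle=False,
                )
                info = zipfile.ZipInfo(
                    name + ".npy", date_time=(1980, 1, 1, 0, 0, 0)
                )
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDatabase":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta.json"]).decode())
            db = cls(params=SiftParams.from_dict(meta["params"]))
            db.excluded = meta["excluded"]
            for i, entry in enumerate(meta["manifest"]):
                kp = npz[f"kp_{i}"]
                fm = FeatureMatrix(
                    id=entry["id"],
                    descriptors=npz[f"desc_{i}"].astype(np.float64),
                    keypoints=[
                        Keypoint(row=r, col=c, scale=s, orientation=o,
                                 response=resp)
                        for r, c, s, o, resp in kp
                    ],
                )
                db.add(fm, source=entry["source"])
        return db


def _features_from_file(
    path: str | Path,
    params: SiftParams,
    chain: str | None = None,
) -> FeatureMatrix:
    trace = load_calpha_trace(path, chain=chain)
    di = compute_distance_matrix(trace)
    img = normalize_matrix(di.D)
    return extract_features(img, params=params, structure_id=trace.id)


def _features_from_trace(
    trace: CalphaTrace, params: SiftParams
) -> FeatureMatrix:
    di = compute_distance_matrix(trace)
    img = normalize_matrix(di.D)
    return extract_features(img, params=params, structure_id=trace.id)


def build_database(
    paths,
    params: SiftParams | None = None,
    chain: str | None = None,
) -> FeatureDatabase:
    """Run the full imaging + extraction pipeline over a file collection.

    Unparseable, empty, or too-small structures are skipped with a logged
    warning and recorded in the database's ``excluded`` list; at least
    one structure must succeed.
    """
    if params is None:
        params = SiftParams()
    db = FeatureDatabase(params=params)
    for p in paths:
        try:
            fm = _features_from_file(p, params, chain=chain)
            db.add(fm, source=str(p))
        except AdamsError as exc:
            logger.warning("skipping %s: %s", p, exc)
            db.excluded.append({"source": str(p), "reason": str(exc)})
    if len(db) == 0:
        raise EmptyDatabaseError("no input structure produced features")
    return db


@dataclass(frozen=True)
class Hit:
    """One ranked database hit."""

    target_id: str
    n_target_features: int
    m: int
    s: float
    z_m: float
    z_s: float
    z_sum: float
    rank: int


@dataclass
class SearchReport:
    """Ranked hit list for one query.

    ``population_size`` is the number of comparisons the z-scores were
    computed over (before any top-k truncation). ``no_features`` flags a
    query outside the method's detection range; ``low_features`` warns
    that the query's keypoint count is below the diagnostic floor.
    """

    query_id: str
    n_query_features: int
    t: float
    population_size: int
    hits: list[Hit] = field(default_factory=list)
    no_features: bool = False
    low_features: bool = False

    def to_tsv(self) -> str:
        lines = [TSV_HEADER]
        for h in self.hits:
            lines.append(
                f"{self.query_id}\t{h.target_id}\t{self.n_query_features}"
                f"\t{h.n_target_features}\t{h.m}\t{h.s:.6f}\t{h.z_m:.6f}"
                f"\t{h.z_s:.6f}\t{h.z_sum:.6f}\t{h.rank}"
            )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def search(
    query,
    db: FeatureDatabase,
    t: float = 0.9,
    top_k: int = 100,
    exclude_self: bool = False,
    chain: str | None = None,
) -> SearchReport:
    """Compare a query structure against every database entry and rank.

    Parameters
    ----------
    query : path-like, CalphaTrace, or FeatureMatrix
        A structure file is run through the full pipeline with the
        database's own SIFT parameters; a precomputed feature matrix is
        used as-is.
    t : float
        Cosine-similarity threshold passed to the matcher.
    top_k : int
        Number of hits retained after ranking. Z-scores are computed over
        the full population first, so truncation never changes them.
    exclude_self : bool
        Drop the database entry whose id equals the query id before
        computing the comparison population.

    Notes
    -----
    Ties on z_sum break by m descending, then target id lexicographic, so
    output order is deterministic. A zero-feature query returns an empty,
    flagged hit list rather than a spurious ranking.
    """
    if top_k < 1:
        raise ParameterError(f"top_k must be >= 1, got {top_k}")
    if len(db) == 0:
        raise EmptyDatabaseError("cannot search an empty database")

    if isinstance(query, FeatureMatrix):
        qfm = query
    elif isinstance(query, CalphaTrace):
        qfm = _features_from_trace(query, db.params)
    else:
        qfm = _features_from_file(query, db.params, chain=chain)

    target_ids = [e["id"] for e in db.manifest]
    if exclude_self:
        target_ids = [tid for tid in target_ids if tid != qfm.id]
        if not target_ids:
            raise EmptyDatabaseError(
                "database holds only the query itself"
            )

    if qfm.n_features == 0:
        return SearchReport(
            query_id=qfm.id, n_query_features=0, t=t,
            population_size=len(target_ids), no_features=True,
        )

    results: list[MatchResult] = [
        match_features(qfm, db.entries[tid], t=t) for tid in target_ids
    ]
    m_vals = np.array([r.m for r in results], dtype=np.float64)
    s_vals = np.array([r.s for r in results], dtype=np.float64)
    z_m = zscore(m_vals)
    z_s = zscore(s_vals)
    z_sum = z_m + z_s

    order = sorted(
        range(len(results)),
        key=lambda i: (-z_sum[i], -results[i].m, results[i].target_id),
    )
    hits = [
        Hit(
            target_id=results[i].target_id,
            n_target_features=results[i].n_target,
            m=results[i].m,
            s=results[i].s,
            z_m=float(z_m[i]),
            z_s=float(z_s[i]),
            z_sum=float(z_sum[i]),
            rank=rank,
        )
        for rank, i in enumerate(order, start=1)
    ]
    report = SearchReport(
        query_id=qfm.id,
        n_query_features=qfm.n_features,
        t=t,
        population_size=len(results),
        hits=hits[:top_k],
        low_features=qfm.n_features < LOW_FEATURE_FLOOR,
    )
    if report.low_features:
        logger.warning(
            "query %s has only %d feature(s); results may be unreliable",
            qfm.id, qfm.n_features,
        )
    return report
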