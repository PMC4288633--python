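"""Domain types and I/O for matched expression / copy-number time courses.

The experimental unit is a set of cell lines (or conditions) assayed at a
common grid of time points, with expression measured for ``p`` genomic
features and, optionally, a matched segmented DNA copy-number profile for the
same samples.  All tables are plain tab-delimited text: matrices carry a
header row of sample ids and a first ``feature_id`` column; feature annotation
is BED-like (``feature_id, chromosome, start, end``, 0-based half-open);
sample annotation has columns ``sample_id, line, time``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SampleAnnotation",
    "FeatureAnnotation",
    "TimeCourseExperiment",
    "MatchMap",
    "load_experiment",
    "write_experiment",
    "match_features",
    "normalize_counts",
]

FAMILIES = ("gaussian", "negative_binomial", "zero_inflated_negative_binomial")


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    line: str
    time: float


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic interval of a feature; coordinates 0-based half-open."""

    feature_id: str
    chromosome: str
    start: int
    end: int
    genome_order: int = -1

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"malformed interval for {self.feature_id}: [{self.start}, {self.end})"
            )


@dataclass
class TimeCourseExperiment:
    """Matched expression / copy-number matrices with sample and feature annotation.

    ``expression`` and ``copy_number`` are ``(p, N)`` arrays over the same
    features and samples; samples are kept sorted by (line, time) — the
    line-major ordering assumed by the per-gene likelihood — and features by
    (chromosome, start).
    """

    expression: np.ndarray
    samples: List[SampleAnnotation]
    features: List[FeatureAnnotation]
    copy_number: Optional[np.ndarray] = None
    family: str = "gaussian"

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        if self.copy_number is not None:
            self.copy_number = np.asarray(self.copy_number, dtype=float)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def p(self) -> int:
        return self.expression.shape[0]

    @property
    def N(self) -> int:
        return self.expression.shape[1]

    @property
    def lines(self) -> np.ndarray:
        return np.array([s.line for s in self.samples])

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples], dtype=float)

    @property
    def n_lines(self) -> int:
        return len(set(s.line for s in self.samples))

    def line_design(self) -> np.ndarray:
        """Cell-line indicator matrix (N x n), cell-means coding."""
        labels = sorted(set(s.line for s in self.samples))
        X = np.zeros((self.N, len(labels)))
        for s_idx, s in enumerate(self.samples):
            X[s_idx, labels.index(s.line)] = 1.0
        return X

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown response family {self.family!r}")
        p, N = self.expression.shape
        if len(self.samples) != N:
            raise ValueError("sample annotation length does not match matrix columns")
        if len(self.features) != p:
            raise ValueError("feature annotation length does not match matrix rows")
        if self.copy_number is not None and self.copy_number.shape != (p, N):
            raise ValueError("copy_number shape differs from expression shape")
        pairs = [(s.line, s.time) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (line, time) pairs in sample annotation")
        for line in set(s.line for s in self.samples):
            times = {s.time for s in self.samples if s.line == line}
            if len(times) < 3:
                raise ValueError(
                    f"line {line!r} has fewer than 3 distinct time points; "
                    "spline fitting refused"
                )
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains missing/non-finite values after loading")
        if self.copy_number is not None and not np.all(np.isfinite(self.copy_number)):
            raise ValueError("copy_number contains missing/non-finite values after loading")
        if self.family != "gaussian":
            if np.any(self.expression < 0) or np.any(self.expression != np.round(self.expression)):
                raise ValueError("count families require non-negative integer expression")

    def subset_samples(self, keep: Sequence[int]) -> "TimeCourseExperiment":
        keep = list(keep)
        return TimeCourseExperiment(
            expression=self.expression[:, keep],
            copy_number=None if self.copy_number is None else self.copy_number[:, keep],
            samples=[self.samples[i] for i in keep],
            features=list(self.features),
            family=self.family,
        )


@dataclass
class MatchMap:
    """Expression-to-copy-number feature pairing by maximal genomic overlap."""

    pairs: List[Tuple[int, int]]
    unmatched: List[int]


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "NA")
        if bad.any():
            row = df.index[bad.idxmax() == df.index][0] if bad.any() else "?"
            raise ValueError(
                f"non-numeric cell in {path} at feature {df.index[np.argmax(bad.values)]!r}, "
                f"column {col!r}"
            )
        df[col] = coerced
    return df


def load_experiment(
    expr_path,
    cn_path=None,
    sample_path=None,
    feature_path=None,
    family: str = "gaussian",
    one_based: bool = False,
) -> TimeCourseExperiment:
    """Load a validated experiment from tab-delimited files.

    Samples are sorted by (line, time) and features by (chromosome, start).
    Feature rows with any missing value (in expression or copy number) are
    dropped with a logged count.  ``one_based=True`` accepts 1-based
    inclusive feature coordinates (GFF-like) and converts them to the internal
    0-based half-open convention.
    """
    expr = _read_matrix(Path(expr_path))
    samp = pd.read_csv(sample_path, sep="\t", dtype={"sample_id": str, "line": str})
    feat = pd.read_csv(feature_path, sep="\t", dtype={"feature_id": str, "chromosome": str})

    expr_samples = set(expr.columns)
    ann_samples = set(samp["sample_id"])
    if expr_samples != ann_samples:
        diff = sorted(expr_samples.symmetric_difference(ann_samples))
        raise ValueError(f"sample sets differ between expression and annotation: {diff}")

    cn = None
    if cn_path is not None:
        cn = _read_matrix(Path(cn_path))
        if set(cn.columns) != expr_samples:
            diff = sorted(set(cn.columns).symmetric_difference(expr_samples))
            raise ValueError(f"sample sets differ between expression and copy number: {diff}")
        cn = cn.reindex(columns=expr.columns)
        missing_feats = expr.index.difference(cn.index)
        if len(missing_feats):
            raise ValueError(
                f"{len(missing_feats)} features present in expression but absent "
                f"from copy number (e.g. {missing_feats[0]!r})"
            )
        cn = cn.reindex(index=expr.index)

    # feature annotation: align, convert coordinates, sort genomically
    feat = feat.set_index("feature_id")
    missing_ann = expr.index.difference(feat.index)
    if len(missing_ann):
        raise ValueError(f"{len(missing_ann)} features lack annotation (e.g. {missing_ann[0]!r})")
    feat = feat.reindex(index=expr.index)
    start = feat["start"].astype(int).to_numpy()
    end = feat["end"].astype(int).to_numpy()
    if one_based:
        start = start - 1  # 1-based inclusive -> 0-based half-open

    # drop features with missing cells
    bad = ~np.isfinite(expr.to_numpy()).all(axis=1)
    if cn is not None:
        bad |= ~np.isfinite(cn.to_numpy()).all(axis=1)
    if bad.any():
        logger.warning("dropping %d feature rows with missing values", int(bad.sum()))
        keep = ~bad
        expr, feat = expr.loc[keep], feat.loc[keep]
        start, end = start[keep], end[keep]
        if cn is not None:
            cn = cn.loc[keep]

    # sort samples by (line, time)
    samp = samp.assign(time=samp["time"].astype(float)).sort_values(["line", "time"])
    order = [list(expr.columns).index(s) for s in samp["sample_id"]]
    expr = expr.iloc[:, order]
    if cn is not None:
        cn = cn.iloc[:, order]

    # sort features by (chromosome, start) and assign within-chromosome rank
    forder = np.lexsort((start, feat["chromosome"].to_numpy()))
    expr = expr.iloc[forder]
    if cn is not None:
        cn = cn.iloc[forder]
    chrom = feat["chromosome"].to_numpy()[forder]
    start, end = start[forder], end[forder]
    features = []
    rank = {}
    for fid, c, s, e in zip(expr.index, chrom, start, end):
        rank[c] = rank.get(c, -1) + 1
        features.append(FeatureAnnotation(str(fid), str(c), int(s), int(e), rank[c]))

    samples = [
        SampleAnnotation(str(r.sample_id), str(r.line), float(r.time))
        for r in samp.itertuples()
    ]
    return TimeCourseExperiment(
        expression=expr.to_numpy(),
        copy_number=None if cn is None else cn.to_numpy(),
        samples=samples,
        features=features,
        family=family,
    )


def write_experiment(exp: TimeCourseExperiment, outdir) -> dict:
    """Write the experiment back to the TSV formats ``load_experiment`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [f.feature_id for f in exp.features]
    cols = [s.sample_id for s in exp.samples]
    paths = {}

    def _dump(name, mat):
        df = pd.DataFrame(mat, index=pd.Index(ids, name="feature_id"), columns=cols)
        path = outdir / name
        df.to_csv(path, sep="\t")
        return path

    paths["expression"] = _dump("expression.tsv", exp.expression)
    if exp.copy_number is not None:
        paths["copy_number"] = _dump("copy_number.tsv", exp.copy_number)
    samp = pd.DataFrame(
        {"sample_id": cols, "line": [s.line for s in exp.samples],
         "time": [s.time for s in exp.samples]}
    )
    paths["samples"] = outdir / "samples.tsv"
    samp.to_csv(paths["samples"], sep="\t", index=False)
    feat = pd.DataFrame(
        {"feature_id": ids, "chromosome": [f.chromosome for f in exp.features],
         "start": [f.start for f in exp.features], "end": [f.end for f in exp.features]}
    )
    paths["features"] = outdir / "features.tsv"
    feat.to_csv(paths["features"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# feature matching
# ---------------------------------------------------------------------------

def match_features(
    expr_features: Sequence[FeatureAnnotation],
    cn_features: Sequence[FeatureAnnotation],
) -> MatchMap:
    """Pair each expression feature with the copy-number feature of maximal overlap.

    Overlap is computed on the same chromosome only; zero overlap leaves the
    feature unmatched.  Ties are broken by smaller copy-number start, then by
    smaller copy-number index.
    """
    by_chrom: dict = {}
    for idx, f in enumerate(cn_features):
        by_chrom.setdefault(f.chromosome, []).append((idx, f))
    pairs, unmatched = [], []
    for eidx, ef in enumerate(expr_features):
        best = None  # (-overlap, start, idx)
        for cidx, cf in by_chrom.get(ef.chromosome, []):
            overlap = min(ef.end, cf.end) - max(ef.start, cf.start)
            if overlap <= 0:
                continue
            key = (-overlap, cf.start, cidx)
            if best is None or key < best:
                best = key
        if best is None:
            unmatched.append(eidx)
        else:
            pairs.append((eidx, best[2]))
    return MatchMap(pairs=pairs, unmatched=unmatched)


# ---------------------------------------------------------------------------
# count normalization
# ---------------------------------------------------------------------------

def normalize_counts(counts: np.ndarray, trim_fraction: float = 0.3) -> np.ndarray:
    """Rescale count columns to a common trimmed-mean library size.

    Each sample column is rescaled so its trimmed mean (``trim_fraction``
    removed from each tail of the within-sample distribution of *non-zero*
    counts) equals the geometric mean of all samples' trimmed means; the
    result is rounded to the nearest integer (half away from zero) to retain
    the count interpretation.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    p, N = counts.shape
    tmeans = np.empty(N)
    for s in range(N):
        col = counts[:, s]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample column {s} has all-zero counts; library unusable")
        tmeans[s] = stats.trim_mean(nz, trim_fraction) if trim_fraction > 0 else nz.mean()
    target = np.exp(np.mean(np.log(tmeans)))
    scaled = counts * (target / tmeans)[None, :]
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
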