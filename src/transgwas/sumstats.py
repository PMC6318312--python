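"""Reading, writing and validation of GWAS summary statistics and companions.

The pipeline is summary-statistics native: its external inputs are per-study
association results (tab-delimited), genomic annotation intervals (BED) and
per-locus LD correlation matrices with a variant index.  This module owns
those formats and the record-level invariants every downstream stage relies
on: autosomal variants only, effect-allele frequency strictly inside (0,1),
positive standard errors, no duplicate variants within a study.

Coordinate conventions: summary statistics carry 1-based positions; BED is
0-based half-open.  ``annotate_variants`` converts with ``pos - 1`` before the
interval lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SumStatsFormatError",
    "QCReport",
    "StudySumStats",
    "AnnotationTrack",
    "LDMatrix",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "harmonise_studies",
    "read_annotations",
    "merge_intervals",
    "annotate_variants",
    "read_ld",
    "write_ld",
]

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Default column-name mapping for summary-statistics TSVs.  Keys are the
#: canonical field names used throughout the package; values are the column
#: headers expected in the file.  INFO and SNP (rsid) are optional.
DEFAULT_DIALECT = {
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
    "info": "INFO",
    "rsid": "SNP",
}

CANONICAL_COLUMNS = [
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "rsid",
    "eaf",
    "beta",
    "se",
    "n",
    "info",
]


class SumStatsFormatError(ValueError):
    """A file does not conform to the expected external format."""


@dataclass
class QCReport:
    """Per-study record-level QC tallies produced at read time."""

    n_read: int = 0
    n_retained: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def add(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)


@dataclass
class StudySumStats:
    """One study's per-variant association summary statistics.

    ``table`` holds the canonical columns: chrom (str), pos (int, 1-based),
    effect_allele, other_allele, rsid, eaf, beta, se, n, info.  The Z-score
    ``beta / se`` is finite for every retained record.
    """

    study_id: str
    ancestry_group: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.table[["chrom", "pos"]])


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (0-based half-open), sorted and merged.

    ``category`` is one of the three annotation groups considered for
    enrichment: genic, tf_binding or cell_type_histone.
    """

    name: str
    category: str
    intervals: pd.DataFrame  # columns chrom (str), start (int), end (int)

    CATEGORIES = ("genic", "tf_binding", "cell_type_histone")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {self.CATEGORIES}"
            )

    @property
    def total_length(self) -> int:
        if self.intervals.empty:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())


@dataclass
class LDMatrix:
    """Pairwise allelic correlations for an ordered list of variants."""

    variants: pd.DataFrame  # columns chrom, pos, effect_allele, other_allele
    r: np.ndarray
    ancestry_group: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.r, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise SumStatsFormatError("LD matrix must be square")
        if m.shape[0] != len(self.variants):
            raise SumStatsFormatError(
                f"LD dimension {m.shape[0]} != index length {len(self.variants)}"
            )
        self.r = m

    @property
    def n_variants(self) -> int:
        return self.r.shape[0]


def _validate_records(table: pd.DataFrame, qc: QCReport, info_min: float) -> pd.DataFrame:
    """Drop rows violating record invariants, tallying reasons in ``qc``."""
    keep = pd.Series(True, index=table.index)

    def drop(mask: pd.Series, reason: str) -> None:
        bad = mask & keep
        qc.add(reason, int(bad.sum()))
        keep[bad] = False

    drop(~table["chrom"].isin(AUTOSOMES), "non_autosomal")
    drop(table["pos"] < 1, "bad_position")
    drop(table["effect_allele"] == table["other_allele"], "identical_alleles")
    numeric = ["eaf", "beta", "se", "n", "info"]
    drop(table[numeric].isna().any(axis=1), "missing_value")
    drop(~((table["eaf"] > 0.0) & (table["eaf"] < 1.0)), "eaf_out_of_range")
    drop(~(table["se"] > 0.0), "nonpositive_se")
    drop(~(table["n"] > 0), "nonpositive_n")
    drop(~((table["info"] >= 0.0) & (table["info"] <= 1.0)), "info_out_of_range")
    drop(table["info"] < info_min, "low_imputation_quality")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = table["beta"] / table["se"]
    drop(~np.isfinite(z), "nonfinite_z")
    drop(table.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"]),
         "duplicate_variant")
    # Two different variants at one site are legitimate (multi-allelic), but a
    # second record at the same (chrom, pos) with the same unordered allele
    # pair is a duplicate in disguise.
    pair = [frozenset(a) for a in zip(table["effect_allele"], table["other_allele"])]
    site = pd.DataFrame({"chrom": table["chrom"], "pos": table["pos"], "pair": pair})
    drop(site.duplicated(), "duplicate_site")
    return table[keep]


def read_sumstats(
    path,
    study_id: str,
    ancestry_group: str,
    dialect: dict | None = None,
    info_min: float = 0.4,
) -> tuple[StudySumStats, QCReport]:
    """Read one study's summary-statistics TSV.

    Rows violating record invariants (including imputation quality below
    ``info_min``, the weakest filter applied to any input study) are dropped
    and tallied in the returned :class:`QCReport`.  A missing mandatory column
    raises :class:`SumStatsFormatError`; an empty file raises ``ValueError``.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype={dialect["chrom"]: str})
    if raw.empty:
        raise ValueError(f"{path}: no records")
    mandatory = ["chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]
    missing = [dialect[k] for k in mandatory if dialect[k] not in raw.columns]
    if missing:
        raise SumStatsFormatError(f"{path}: missing mandatory columns {missing}")

    table = pd.DataFrame(
        {
            "chrom": raw[dialect["chrom"]].astype(str).str.removeprefix("chr"),
            "pos": pd.to_numeric(raw[dialect["pos"]], errors="coerce"),
            "effect_allele": raw[dialect["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[dialect["other_allele"]].astype(str).str.upper(),
            "rsid": raw[dialect["rsid"]].astype(str)
            if dialect["rsid"] in raw.columns
            else "",
            "eaf": pd.to_numeric(raw[dialect["eaf"]], errors="coerce"),
            "beta": pd.to_numeric(raw[dialect["beta"]], errors="coerce"),
            "se": pd.to_numeric(raw[dialect["se"]], errors="coerce"),
            "n": pd.to_numeric(raw[dialect["n"]], errors="coerce"),
            "info": pd.to_numeric(raw[dialect["info"]], errors="coerce")
            if dialect["info"] in raw.columns
            else 1.0,
        }
    )
    qc = QCReport(n_read=len(table))
    bad_pos = table["pos"].isna()
    qc.add("unparseable_position", int(bad_pos.sum()))
    table = table[~bad_pos]
    table["pos"] = table["pos"].astype(np.int64)
    table = _validate_records(table, qc, info_min=info_min)
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    qc.n_retained = len(table)
    return StudySumStats(study_id, ancestry_group, table), qc


def write_sumstats(ss: StudySumStats, path) -> None:
    """Write canonical summary statistics as TSV (floats at 6 sig. digits)."""
    out = ss.table.copy()
    out.columns = [DEFAULT_DIALECT.get(c, c.upper()) for c in out.columns]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def harmonise_studies(
    studies: list[StudySumStats],
) -> tuple[list[StudySumStats], dict[str, int]]:
    """Align effect alleles across studies to the first study's orientation.

    At each (chrom, pos) seen in an earlier study, a later record with the
    alleles swapped is flipped (beta sign negated, eaf complemented).  Strand
    flips are never attempted; a record whose allele pair cannot be matched to
    the reference orientation at a shared site is dropped and counted.  Sites
    absent from the reference so far define the orientation for later studies.
    """
    orientation: dict[tuple[str, int], tuple[str, str]] = {}
    counts = {"flipped": 0, "dropped_mismatch": 0}
    out: list[StudySumStats] = []
    for ss in studies:
        t = ss.table.copy()
        keys = list(zip(t["chrom"], t["pos"]))
        eas = t["effect_allele"].to_numpy()
        oas = t["other_allele"].to_numpy()
        flip = np.zeros(len(t), dtype=bool)
        drop = np.zeros(len(t), dtype=bool)
        for i, key in enumerate(keys):
            ref = orientation.get(key)
            if ref is None:
                orientation[key] = (eas[i], oas[i])
            elif (eas[i], oas[i]) == ref:
                pass
            elif (oas[i], eas[i]) == ref:
                flip[i] = True
            else:
                drop[i] = True
        if flip.any():
            t.loc[flip, "beta"] = -t.loc[flip, "beta"]
            t.loc[flip, "eaf"] = 1.0 - t.loc[flip, "eaf"]
            t.loc[flip, ["effect_allele", "other_allele"]] = t.loc[
                flip, ["other_allele", "effect_allele"]
            ].to_numpy()
            counts["flipped"] += int(flip.sum())
        if drop.any():
            t = t[~drop]
            counts["dropped_mismatch"] += int(drop.sum())
        out.append(StudySumStats(ss.study_id, ss.ancestry_group, t.reset_index(drop=True)))
    return out, counts


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Sort and union overlapping/adjacent half-open intervals per chromosome.

    Idempotent: merging a merged table returns it unchanged.
    """
    if intervals.empty:
        return intervals.reset_index(drop=True)
    parts = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        g = grp.sort_values(["start", "end"]).to_numpy()[:, 1:3].astype(np.int64)
        starts, ends = [], []
        cur_s, cur_e = g[0]
        for s, e in g[1:]:
            if s <= cur_e:  # overlap or adjacency unions
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        parts.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(parts, ignore_index=True)


def read_annotations(
    paths: list,
    names: list[str],
    categories: list[str],
) -> list[AnnotationTrack]:
    """Read BED3+ files into sorted, merged annotation tracks.

    BED intervals are 0-based half-open.  ``start >= end`` raises
    :class:`SumStatsFormatError` naming the offending line.
    """
    if not (len(paths) == len(names) == len(categories)):
        raise ValueError("paths, names and categories must have equal length")
    tracks = []
    for path, name, category in zip(paths, names, categories):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise SumStatsFormatError(
                        f"{path}:{lineno}: BED needs >= 3 columns"
                    )
                chrom = fields[0].removeprefix("chr")
                start, end = int(fields[1]), int(fields[2])
                if start < 0:
                    raise SumStatsFormatError(f"{path}:{lineno}: negative start")
                if start >= end:
                    raise SumStatsFormatError(
                        f"{path}:{lineno}: start {start} >= end {end}"
                    )
                rows.append((chrom, start, end))
        intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        tracks.append(AnnotationTrack(name, category, merge_intervals(intervals)))
    return tracks


def annotate_variants(
    variants: pd.DataFrame, tracks: list[AnnotationTrack]
) -> np.ndarray:
    """Binary membership matrix z (variants x tracks).

    ``z[v, k] = 1`` iff the variant's 1-based position, converted to 0-based,
    lies inside a half-open interval of track k on the same chromosome.
    """
    n = len(variants)
    z = np.zeros((n, len(tracks)), dtype=np.int8)
    pos0 = variants["pos"].to_numpy(dtype=np.int64) - 1
    chroms = variants["chrom"].to_numpy()
    for k, track in enumerate(tracks):
        for chrom, grp in track.intervals.groupby("chrom"):
            sel = np.flatnonzero(chroms == chrom)
            if sel.size == 0:
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # merged intervals are disjoint and sorted: a position is covered
            # iff it falls before the end of the interval whose start precedes it
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            inside = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
            z[sel[inside], k] = 1
    return z


def read_ld(
    matrix_path, index_path, ancestry_group: str = "", atol: float = 1e-6
) -> LDMatrix:
    """Read a whitespace-delimited square correlation matrix plus variant index.

    Symmetry is enforced by averaging ``r`` with its transpose (a warning is
    emitted if the asymmetry exceeds ``atol``); the diagonal is reset to 1.
    Entries with ``|r| > 1`` (beyond round-off) are rejected.
    """
    r = np.loadtxt(matrix_path, ndmin=2)
    if r.shape[0] != r.shape[1]:
        raise SumStatsFormatError(f"{matrix_path}: matrix is not square {r.shape}")
    index = pd.read_csv(
        index_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "pos", "effect_allele", "other_allele"],
        dtype={"chrom": str},
    )
    if len(index) != r.shape[0]:
        raise SumStatsFormatError(
            f"{index_path}: {len(index)} variants for a "
            f"{r.shape[0]}x{r.shape[1]} matrix"
        )
    if np.any(np.abs(r) > 1.0 + 1e-9):
        raise SumStatsFormatError(f"{matrix_path}: correlation entries exceed |1|")
    asym = np.max(np.abs(r - r.T)) if r.size else 0.0
    if asym > atol:
        import warnings

        warnings.warn(f"{matrix_path}: max asymmetry {asym:.3g} > {atol:.0e}")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(index, r, ancestry_group)


def write_ld(ld: LDMatrix, matrix_path, index_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.6g")
    ld.variants[["chrom", "pos", "effect_allele", "other_allele"]].to_csv(
        index_path, sep="\t", header=False, index=False
    )
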