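"""Reading of variant records, depth tables, manifests and CDS intervals.

Applies the inclusion filters of the variant-calling protocol the pipeline
mirrors: records must carry a Phred quality strictly greater than 25, and
must satisfy the caller minima — alternate observations >= 4, total depth
>= 5, VAF >= 0.2 (boundary values pass, as befits stated *minimums*).
Coordinates follow the usual conventions: VCF and the depth table are
1-based, BED is 0-based half-open; the conversion lives in one place
(:func:`bed_interval_contains`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    alt_obs: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if not 0 <= self.alt_obs <= self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_obs {self.alt_obs} outside [0, depth={self.depth}]"
            )
        if self.qual < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative quality")

    @property
    def vaf(self) -> float:
        return self.alt_obs / self.depth if self.depth else 0.0

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class SiteSet:
    """Ordered unique (chrom, pos, ref, alt) keys, sorted by (chrom, pos)."""

    def __init__(self, keys: Iterable[tuple[str, int, str, str]]):
        seen = dict.fromkeys(keys)  # preserves first occurrence, dedups
        self.keys: list[tuple[str, int, str, str]] = sorted(
            seen, key=lambda k: (k[0], k[1], k[2], k[3])
        )
        self.index = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)

    def __contains__(self, key) -> bool:
        return key in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, SiteSet) and self.keys == other.keys

    def positions(self) -> list[tuple[str, int]]:
        return [(c, p) for c, p, _, _ in self.keys]


def union_sites(records_by_sample: dict[str, Sequence[VariantRecord]]) -> SiteSet:
    """Union of sites across all samples; invariant to sample input order."""
    return SiteSet(r.site_key for recs in records_by_sample.values() for r in recs)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _record_depth_alt(rec: "pysam.VariantRecord") -> tuple[int, int]:
    """DP and summed alternate observations for one pysam record.

    INFO DP/AO are preferred (Freebayes semantics for per-sample files);
    per-sample FORMAT AD/DP are the fallback when AO is absent.
    """
    where = f"{rec.chrom}:{rec.pos}"

    def info_get(key):
        # pysam raises rather than returning None for keys absent from the
        # header entirely
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):
            return None

    depth = info_get("DP")
    alt_obs = info_get("AO")
    if alt_obs is not None:
        alt_obs = sum(int(a) for a in np.atleast_1d(alt_obs))
    elif rec.samples:
        sample = rec.samples[next(iter(rec.samples))]
        ad = sample.get("AD")
        if ad is not None:
            alt_obs = sum(int(a) for a in ad[1:])
            if depth is None:
                depth = sum(int(a) for a in ad)
        if depth is None:
            depth = sample.get("DP")
    if depth is None:
        raise ValueError(f"{where}: record carries no DP (INFO or FORMAT)")
    if alt_obs is None:
        raise ValueError(f"{where}: record carries no AO/AD alternate counts")
    return int(depth), int(alt_obs)


def read_sample_variants(vcf_source: str | Path, min_qual: float = 25.0) -> list[VariantRecord]:
    """Read one sample's VCF, keeping records with qual strictly > ``min_qual``.

    Multi-allelic records are collapsed to a single alternate with
    ``alt_obs`` summed over all alternates (ALT rendered comma-joined).
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_source)) as vf:
        for rec in vf:
            qual = rec.qual if rec.qual is not None else 0.0
            if not qual > min_qual:
                continue
            depth, alt_obs = _record_depth_alt(rec)
            alts = ",".join(rec.alts) if rec.alts else "."
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts,
                    qual=float(qual),
                    depth=depth,
                    alt_obs=alt_obs,
                )
            )
    return out


def apply_caller_thresholds(
    records: Iterable[VariantRecord],
    min_alt: int = 4,
    min_depth: int = 5,
    min_vaf: float = 0.2,
) -> list[VariantRecord]:
    """Keep records with alt_obs >= min_alt, depth >= min_depth and
    VAF >= min_vaf; boundary values pass."""
    return [
        r
        for r in records
        if r.alt_obs >= min_alt and r.depth >= min_depth and r.vaf >= min_vaf
    ]


def records_from_frame(frame: pd.DataFrame) -> list[VariantRecord]:
    """Adapt the simulator's record DataFrame to :class:`VariantRecord` lists."""
    return [
        VariantRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            qual=float(r.qual),
            depth=int(r.depth),
            alt_obs=int(r.alt_obs),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open) and site restriction
# ---------------------------------------------------------------------------


def read_bed(bed_source: str | Path) -> list[tuple[str, int, int]]:
    """Parse a BED3 file into (chrom, start, end) with per-line validation."""
    intervals: list[tuple[str, int, int]] = []
    with open(bed_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"BED line {lineno}: invalid interval [{start}, {end})")
            intervals.append((chrom, start, end))
    return intervals


def bed_interval_contains(start: int, end: int, pos_1based: int) -> bool:
    """A 0-based half-open [start, end) contains 1-based position p iff
    start < p <= end."""
    return start < pos_1based <= end


def restrict_to_intervals(
    site_set: SiteSet, intervals: str | Path | list[tuple[str, int, int]]
) -> SiteSet:
    """Retain sites that fall inside any interval; order preserved.

    Idempotent: restricting an already-restricted set is a no-op.
    """
    if not isinstance(intervals, list):
        intervals = read_bed(intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    kept = [
        key
        for key in site_set.keys
        if any(
            bed_interval_contains(s, e, key[1]) for s, e in by_chrom.get(key[0], ())
        )
    ]
    return SiteSet(kept)


# ---------------------------------------------------------------------------
# depth table and manifest
# ---------------------------------------------------------------------------


def read_depth_table(
    tsv_source: str | Path, site_set: SiteSet, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Depth table aligned to ``site_set`` x ``sample_ids``.

    Input rows are keyed ``CHROM:POS``; sites absent from the table become
    missing (NaN) for all samples — distinct from a present depth of 0.
    """
    raw = pd.read_csv(tsv_source, sep="\t", index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate site row in depth table: {dup}")
    missing_cols = [s for s in sample_ids if s not in raw.columns]
    if missing_cols:
        raise ValueError(f"depth table lacks sample columns: {missing_cols}")
    numeric = raw[list(sample_ids)].astype(float)
    if (numeric.to_numpy() < 0).any():
        raise ValueError("negative depth in depth table")
    row_keys = [f"{c}:{p}" for c, p in site_set.positions()]
    aligned = numeric.reindex(row_keys)
    aligned.index = pd.Index(row_keys, name="site")
    return aligned


def packaged_data(name: str) -> Path:
    """Path to a data file shipped with the package (manifests, fixtures)."""
    from importlib.resources import files

    return Path(str(files("vafclust") / "data" / name))


def read_manifest(tsv_source: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV (sample_id, taxon, section, source)."""
    manifest = pd.read_csv(tsv_source, sep="\t", dtype=str)
    required = {"sample_id", "taxon", "section", "source"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return manifest
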