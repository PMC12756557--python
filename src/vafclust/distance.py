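"""Sample x site VAF matrix and the pairwise-complete normalized distance.

The distance between two samples is the root-mean-square difference of
their VAF vectors over the sites both samples cover adequately:

    d_ij = sqrt( (1/|P_ij|) * sum_{p in P_ij} (v_i(p) - v_j(p))^2 )

where P_ij is the set of positions with depth >= 8 (default) in *both*
samples.  Because VAF lies in [0, 1], so does d.  Normalization sits inside
the square root, so the distance is invariant to the number of usable
sites.  Each pair has its own site set (pairwise-complete masking); the
per-pair usable-site counts N_ij are kept alongside the distances, and a
pair with too few usable sites is flagged undefined rather than imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import SiteSet, VariantRecord


@dataclasses.dataclass
class VAFMatrix:
    """Per-sample VAF vectors with the aligned depth table.

    ``vaf`` is (n_samples, n_sites) in [0, 1]; ``depth`` is float with NaN
    marking missing coverage information.  A covered site without a
    surviving variant record holds VAF 0.0 (reference-homozygous) under the
    default ``uncalled="ref"`` policy, or NaN-masked under
    ``uncalled="missing"``.
    """

    samples: list[str]
    sites: SiteSet
    vaf: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.vaf.shape
        if len(self.samples) != n or len(self.sites) != m or self.depth.shape != (n, m):
            raise ValueError("vaf/depth/sample/site shapes disagree")
        defined = ~np.isnan(self.depth)
        vals = self.vaf[defined & ~np.isnan(self.vaf)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("VAF values outside [0, 1]")

    def subset_sites(self, idx: np.ndarray) -> "VAFMatrix":
        """Column subset/resample; used by the bootstrap."""
        sub = object.__new__(VAFMatrix)
        sub.samples = self.samples
        sub.sites = self.sites  # identity of resampled columns is positional
        sub.vaf = self.vaf[:, idx]
        sub.depth = self.depth[:, idx]
        return sub


def build_vaf_matrix(
    records_by_sample: dict[str, Sequence[VariantRecord]],
    depth_table: pd.DataFrame,
    site_set: SiteSet,
    uncalled: str = "ref",
) -> VAFMatrix:
    """Assemble the VAF matrix from filtered records and the depth table.

    ``uncalled`` controls sites with adequate coverage but no surviving
    record: ``"ref"`` (default) assigns VAF 0.0, treating the sample as
    reference-homozygous there; ``"missing"`` masks them, so they drop out
    of every pair involving the sample.
    """
    if uncalled not in ("ref", "missing"):
        raise ValueError(f"unknown uncalled mode: {uncalled!r}")
    samples = list(records_by_sample)
    n, m = len(samples), len(site_set)
    missing_cols = [s for s in samples if s not in depth_table.columns]
    if missing_cols:
        raise ValueError(f"depth table lacks sample columns: {missing_cols}")
    depth = depth_table[samples].to_numpy(dtype=float).T  # (n, m)
    if depth.shape != (n, m):
        raise ValueError("depth table rows not aligned to site_set")
    vaf = np.zeros((n, m), dtype=float)
    called = np.zeros((n, m), dtype=bool)
    for i, sample in enumerate(samples):
        for rec in records_by_sample[sample]:
            j = site_set.index.get(rec.site_key)
            if j is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} ({rec.ref}>{rec.alt}) of sample "
                    f"{sample} is not in the site union"
                )
            vaf[i, j] = rec.vaf
            called[i, j] = True
    if uncalled == "missing":
        depth = depth.copy()
        depth[~called] = np.nan
    vaf[np.isnan(depth)] = np.nan
    return VAFMatrix(samples=samples, sites=site_set, vaf=vaf, depth=depth)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair usable-site counts.

    ``d`` holds NaN where a pair is undefined (too few co-covered sites);
    ``defined`` flags usable pairs; the diagonal is exactly zero.
    """

    samples: list[str]
    d: np.ndarray
    n_sites_used: np.ndarray
    defined: np.ndarray

    @property
    def all_defined(self) -> bool:
        off = ~np.eye(len(self.samples), dtype=bool)
        return bool(self.defined[off].all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy convention)."""
        iu = np.triu_indices(len(self.samples), k=1)
        return self.d[iu]


def pairwise_distance(
    m: VAFMatrix, min_pair_depth: int = 8, min_sites: int = 1
) -> DistanceMatrix:
    """Masked pairwise-complete RMS distance between VAF vectors.

    A site enters pair (i, j) iff both depths are non-missing and
    >= ``min_pair_depth``.  Pairs with fewer than ``min_sites`` usable sites
    are flagged undefined; if every pair is undefined the matrix is useless
    and an error is raised.
    """
    n = len(m.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    cover = (np.nan_to_num(m.depth, nan=-1.0) >= min_pair_depth).astype(float)
    v = np.nan_to_num(m.vaf, nan=0.0) * cover
    sq = np.nan_to_num(m.vaf, nan=0.0) ** 2 * cover
    counts = cover @ cover.T
    cross = v @ v.T
    a = sq @ cover.T
    ss = a + a.T - 2.0 * cross  # sum over P_ij of (v_i - v_j)^2
    np.clip(ss, 0.0, None, out=ss)

    defined = counts >= max(min_sites, 1)
    np.fill_diagonal(defined, True)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(ss / counts)
    d[~defined] = np.nan
    np.fill_diagonal(d, 0.0)
    d = np.where(defined, d, np.nan)
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite float matmul non-associativity
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)

    off = ~np.eye(n, dtype=bool)
    if not defined[off].any():
        raise ValueError("no co-covered positions for any sample pair")
    return DistanceMatrix(
        samples=list(m.samples),
        d=d,
        n_sites_used=counts.astype(np.int64),
        defined=defined,
    )


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the distance matrix as a square TSV (6 decimals) plus a
    full-precision sidecar (`<path>.full.tsv`, %.17g) and the per-pair site
    counts (`<path>.nsites.tsv`)."""
    path = Path(path)
    dm.to_frame().to_csv(path, sep="\t", float_format="%.6f")
    full = pd.DataFrame(dm.d, index=dm.samples, columns=dm.samples)
    full.to_csv(path.with_suffix(path.suffix + ".full.tsv"), sep="\t", float_format="%.17g")
    pd.DataFrame(dm.n_sites_used, index=dm.samples, columns=dm.samples).to_csv(
        path.with_suffix(path.suffix + ".nsites.tsv"), sep="\t"
    )


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_distance_tsv`,
    preferring the lossless sidecar when present."""
    path = Path(path)
    full = path.with_suffix(path.suffix + ".full.tsv")
    frame = pd.read_csv(
        full if full.exists() else path, sep="\t", index_col=0,
        float_precision="round_trip",
    )
    samples = list(frame.index)
    d = frame.to_numpy(dtype=float)
    nsites_path = path.with_suffix(path.suffix + ".nsites.tsv")
    if nsites_path.exists():
        n_sites = pd.read_csv(nsites_path, sep="\t", index_col=0).to_numpy(dtype=np.int64)
    else:
        n_sites = np.zeros_like(d, dtype=np.int64)
    defined = ~np.isnan(d)
    return DistanceMatrix(samples=samples, d=d, n_sites_used=n_sites, defined=defined)
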