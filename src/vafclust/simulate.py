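"""Synthetic multi-species cohort generator with read-level sequencing emulation.

Generates diploid individuals from diverged populations plus F1 inter-species
hybrids, draws per-site read depths and alternate-read counts, and emits
per-sample variant records that survive the same caller thresholds the
downstream filters apply (minimum alternate observations 4, minimum total
depth 5, minimum VAF 0.2).  Population allele frequencies follow the
Balding–Nichols model: an ancestral frequency ``p`` per site, and each
population draws ``q ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that ``F`` controls
drift-driven divergence (``F -> 1`` fixes alternative alleles, ``F -> 0``
keeps every population at the ancestral frequency).

The generator exists so that every downstream stage — filtering, the masked
VAF distance, Ward.D2 clustering and bootstrap support — can be tested
against known population structure without any external sequencing data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

CONTIG = "chr_syn"

#: caller-threshold defaults the emitted records are guaranteed to satisfy
MIN_ALT_OBS = 4
MIN_TOTAL_DEPTH = 5
MIN_VAF = 0.2

#: Phred quality written into every emitted record; the quality filter path
#: is exercised separately with a low-quality fixture.
RECORD_QUAL = 60.0


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``hybrids`` is a list of ``(parent_a, parent_b, n_samples)`` tuples with
    0-based parent population indices; each hybrid sample is an F1 carrying
    one allele drawn from each parent's frequency at every site.
    """

    n_species: int = 3
    samples_per_species: int = 4
    hybrids: tuple[tuple[int, int, int], ...] = ()
    n_sites: int = 2000
    divergence_F: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    mean_depth: float = 30.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError("divergence_F must lie in the open interval (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for a, b, k in self.hybrids:
            if not (0 <= a < self.n_species and 0 <= b < self.n_species):
                raise ValueError(
                    f"hybrid parents ({a}, {b}) reference non-existent species"
                )
            if k < 1:
                raise ValueError("hybrid sample_count must be >= 1")
        # normalise hybrids to a hashable tuple-of-tuples
        object.__setattr__(self, "hybrids", tuple(tuple(h) for h in self.hybrids))


@dataclasses.dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``sample_labels`` maps sample id to its population label
    (``spNN`` for pure samples, ``spAAxspBB_F1`` for hybrids).
    ``depth_full`` / ``alt_full`` keep the raw per-sample read draws at every
    simulated site (not just emitted ones) so tests can re-apply the caller
    thresholds independently of the emission logic.
    """

    sample_labels: dict[str, str]
    species_site_freqs: np.ndarray  # (K, m) in [0, 1]
    genotypes: np.ndarray  # (n, m) allele dose in {0, 1, 2}
    depth_full: np.ndarray  # (n, m) ints
    alt_full: np.ndarray  # (n, m) ints
    positions: np.ndarray  # (m,) 1-based positions on CONTIG

    @property
    def species_of(self) -> dict[str, str]:
        return dict(self.sample_labels)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_labels": self.sample_labels,
                "species_site_freqs": self.species_site_freqs.tolist(),
                "genotypes": self.genotypes.tolist(),
            }
        )


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Sample ids and their truth labels, pure samples first then hybrids."""
    names, labels = [], []
    for s in range(config.n_species):
        for i in range(config.samples_per_species):
            names.append(f"sp{s + 1:02d}_{i + 1:02d}")
            labels.append(f"sp{s + 1:02d}")
    for a, b, k in config.hybrids:
        lab = f"sp{a + 1:02d}xsp{b + 1:02d}_F1"
        for i in range(k):
            names.append(f"hyb{a + 1:02d}x{b + 1:02d}_{i + 1:02d}")
            labels.append(lab)
    return names, labels


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortTruth, dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(truth, variant_records, depth_table, manifest)`` where
    ``variant_records`` maps sample id to a DataFrame of emitted records
    (columns chrom, pos, ref, alt, qual, depth, alt_obs), ``depth_table`` is
    the per-sample depth at the union of emitted sites (rows ``CHROM:POS``),
    and ``manifest`` carries sample_id / taxon / section / source columns with
    the truth label as taxon.

    One ``numpy`` Generator seeded once drives every draw; draws are made in
    fixed vectorised order (ancestral freqs, population freqs, genotypes
    sample-block by sample-block, depths, alt reads), so identical config +
    seed reproduces the cohort bit-for-bit.  Adding a sample or species
    re-shuffles later draws; per-sample draw stability across config changes
    is deliberately not guaranteed.
    """
    rng = np.random.default_rng(config.seed)
    K, m = config.n_species, config.n_sites
    names, labels = _sample_names(config)
    n = len(names)

    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=m)
    F = config.divergence_F
    scale = (1.0 - F) / F
    q = rng.beta(np.broadcast_to(p * scale, (K, m)), np.broadcast_to((1.0 - p) * scale, (K, m)))
    # beta() can return exact 0/1 only in degenerate float cases; clip to keep
    # binomial parameters valid
    q = np.clip(q, 0.0, 1.0)

    genotypes = np.empty((n, m), dtype=np.int64)
    row = 0
    for s in range(K):
        for _ in range(config.samples_per_species):
            genotypes[row] = rng.binomial(2, q[s])
            row += 1
    for a, b, k in config.hybrids:
        for _ in range(k):
            genotypes[row] = rng.binomial(1, q[a]) + rng.binomial(1, q[b])
            row += 1

    depth = rng.poisson(config.mean_depth, size=(n, m))
    e = config.error_rate
    alt_prob = (genotypes / 2.0) * (1.0 - e) + (1.0 - genotypes / 2.0) * e
    alt = rng.binomial(depth, alt_prob)

    positions = np.arange(1, m + 1, dtype=np.int64)
    truth = CohortTruth(
        sample_labels=dict(zip(names, labels)),
        species_site_freqs=q,
        genotypes=genotypes,
        depth_full=depth,
        alt_full=alt,
        positions=positions,
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    emitted = (alt >= MIN_ALT_OBS) & (depth >= MIN_TOTAL_DEPTH) & (vaf >= MIN_VAF)

    union = np.flatnonzero(emitted.any(axis=0))
    records: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(names):
        idx = np.flatnonzero(emitted[i])
        records[name] = pd.DataFrame(
            {
                "chrom": CONTIG,
                "pos": positions[idx],
                "ref": "A",
                "alt": "T",
                "qual": RECORD_QUAL,
                "depth": depth[i, idx],
                "alt_obs": alt[i, idx],
            }
        )

    depth_table = pd.DataFrame(
        depth[:, union].T,
        index=[f"{CONTIG}:{positions[j]}" for j in union],
        columns=names,
    )
    depth_table.index.name = "site"

    manifest = pd.DataFrame(
        {
            "sample_id": names,
            "taxon": labels,
            "section": "synthetic",
            "source": "simulated",
        }
    )
    return truth, records, depth_table, manifest


def simulate_manifest_cohort(
    manifest: pd.DataFrame,
    n_sites: int = 2000,
    divergence_F: float = 0.4,
    mean_depth: float = 30.0,
    error_rate: float = 0.005,
    seed: int = 0,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[CohortTruth, dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort whose samples and taxa follow an existing manifest.

    Each distinct taxon in the manifest becomes one population (hybrid
    cultivar taxa are treated as populations of their own — appropriate for
    stabilised, clonally propagated hybrids).  Sample ids are taken from the
    manifest, so downstream artifacts carry the manifest's naming.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    taxa = list(dict.fromkeys(manifest["taxon"]))
    rng = np.random.default_rng(seed)
    K, m = len(taxa), int(n_sites)
    if m < 1:
        raise ValueError("n_sites must be >= 1")

    lo, hi = ancestral_freq_range
    p = rng.uniform(lo, hi, size=m)
    scale = (1.0 - divergence_F) / divergence_F
    q = rng.beta(
        np.broadcast_to(p * scale, (K, m)),
        np.broadcast_to((1.0 - p) * scale, (K, m)),
    )
    q = np.clip(q, 0.0, 1.0)

    names = list(manifest["sample_id"])
    labels = list(manifest["taxon"])
    n = len(names)
    genotypes = np.empty((n, m), dtype=np.int64)
    for i, tax in enumerate(labels):
        genotypes[i] = rng.binomial(2, q[taxa.index(tax)])

    depth = rng.poisson(mean_depth, size=(n, m))
    alt_prob = (genotypes / 2.0) * (1.0 - error_rate) + (1.0 - genotypes / 2.0) * error_rate
    alt = rng.binomial(depth, alt_prob)
    positions = np.arange(1, m + 1, dtype=np.int64)

    truth = CohortTruth(
        sample_labels=dict(zip(names, labels)),
        species_site_freqs=q,
        genotypes=genotypes,
        depth_full=depth,
        alt_full=alt,
        positions=positions,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    emitted = (alt >= MIN_ALT_OBS) & (depth >= MIN_TOTAL_DEPTH) & (vaf >= MIN_VAF)
    union = np.flatnonzero(emitted.any(axis=0))

    records = {}
    for i, name in enumerate(names):
        idx = np.flatnonzero(emitted[i])
        records[name] = pd.DataFrame(
            {
                "chrom": CONTIG,
                "pos": positions[idx],
                "ref": "A",
                "alt": "T",
                "qual": RECORD_QUAL,
                "depth": depth[i, idx],
                "alt_obs": alt[i, idx],
            }
        )
    depth_table = pd.DataFrame(
        depth[:, union].T,
        index=[f"{CONTIG}:{positions[j]}" for j in union],
        columns=names,
    )
    depth_table.index.name = "site"
    return truth, records, depth_table, manifest.reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization of the simulated cohort to on-disk formats
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_sample_vcf(records: pd.DataFrame, path: str | Path, contig_length: int) -> None:
    """Write one sample's emitted records as a minimal uncompressed VCF."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER.format(contig=CONTIG, length=contig_length))
        for r in records.itertuples(index=False):
            qual = f"{r.qual:g}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t"
                f"DP={r.depth};AO={r.alt_obs}\n"
            )


def write_cohort(
    truth: CohortTruth,
    records: dict[str, pd.DataFrame],
    depth_table: pd.DataFrame,
    manifest: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Serialize a simulated cohort: one VCF per sample, a depth TSV, a
    manifest TSV and a truth JSON.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_length = int(truth.positions[-1])
    paths: dict[str, Path] = {}
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for name, recs in records.items():
        p = vcf_dir / f"{name}.vcf"
        write_sample_vcf(recs, p, contig_length)
        paths[f"vcf:{name}"] = p
    depth_path = outdir / "depth.tsv"
    depth_table.to_csv(depth_path, sep="\t")
    paths["depth"] = depth_path
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    paths["manifest"] = manifest_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths
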