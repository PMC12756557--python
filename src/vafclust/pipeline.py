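"""End-to-end orchestration: simulate/load -> filter -> VAF matrix ->
masked distance -> ward.D2 tree -> bootstrap support, with a run report.

The mapping-quality (25) and base-quality (20) thresholds belong to the
read-alignment/calling stage upstream of this pipeline's inputs; they are
recorded in the report for provenance but never applied here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import distance as _distance
from . import hierarchy as _hierarchy
from . import simulate as _simulate
from . import variant_io as _io

logger = logging.getLogger("vafclust")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``vcf_dir`` (with ``depth_table`` and ``manifest``) or
    ``simulation`` must be set.  Threshold defaults mirror the variant
    inclusion protocol: quality strictly > 25, alternate observations >= 4,
    depth >= 5, VAF >= 0.2, pair mask depth >= 8.
    """

    outdir: str = "vafclust_out"
    vcf_dir: str | None = None
    depth_table: str | None = None
    manifest: str | None = None
    bed: str | None = None
    simulation: _simulate.SimulationConfig | None = None
    min_qual: float = 25.0
    min_alt: int = 4
    min_depth: int = 5
    min_vaf: float = 0.2
    min_pair_depth: int = 8
    bootstrap_B: int = 1000
    seed: int = 0
    uncalled: str = "ref"
    # upstream-only thresholds, recorded for provenance, never applied
    mapping_q: float = 25.0
    base_q: float = 20.0

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_alt", "min_depth", "min_vaf", "min_pair_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        has_paths = self.vcf_dir is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("set exactly one of vcf_dir or simulation")
        if has_paths and (self.depth_table is None or self.manifest is None):
            raise ValueError("vcf_dir input requires depth_table and manifest")


def validate_manifest(tsv_source: str | Path | pd.DataFrame) -> dict:
    """Summarise a sample manifest: sample count, distinct taxa,
    per-section counts.  Rejects empty manifests and duplicate sample ids."""
    manifest = (
        tsv_source
        if isinstance(tsv_source, pd.DataFrame)
        else _io.read_manifest(tsv_source)
    )
    if manifest.empty:
        raise ValueError("manifest is empty")
    dup = manifest["sample_id"][manifest["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated sample id in manifest: {dup.iloc[0]}")
    return {
        "n_samples": int(len(manifest)),
        "n_taxa": int(manifest["taxon"].nunique()),
        "per_section": manifest.groupby("section")["taxon"].count().to_dict(),
    }


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Return (records_by_sample, depth_table_raw_path, manifest, truth-or-None)."""
    if config.simulation is not None:
        truth, rec_frames, depth_table, manifest = _simulate.simulate_cohort(
            config.simulation
        )
        paths = _simulate.write_cohort(truth, rec_frames, depth_table, manifest, outdir / "cohort")
        vcf_dir = (outdir / "cohort" / "vcf")
        depth_path = paths["depth"]
        manifest = manifest
    else:
        vcf_dir = Path(config.vcf_dir)
        depth_path = Path(config.depth_table)
        manifest = _io.read_manifest(config.manifest)
        truth = None
    records_raw = {}
    for sample in manifest["sample_id"]:
        vcf_path = vcf_dir / f"{sample}.vcf"
        if not vcf_path.exists():
            raise FileNotFoundError(f"no VCF for sample {sample}: {vcf_path}")
        records_raw[sample] = _io.read_sample_variants(vcf_path, min_qual=config.min_qual)
    return records_raw, depth_path, manifest, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes the artifact bundle and returns a
    result dict with the report and in-memory objects."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "thresholds": {
            "min_qual_strictly_greater": config.min_qual,
            "min_alt": config.min_alt,
            "min_depth": config.min_depth,
            "min_vaf": config.min_vaf,
            "min_pair_depth": config.min_pair_depth,
            "mapping_q_upstream_only": config.mapping_q,
            "base_q_upstream_only": config.base_q,
            "uncalled_policy": config.uncalled,
        },
        "seed": config.seed,
        "stages": {},
    }

    records_raw, depth_path, manifest, truth = _load_inputs(config, outdir)
    report["manifest"] = validate_manifest(manifest)
    n_read = sum(len(v) for v in records_raw.values())
    report["stages"]["records_after_qual_filter"] = n_read
    logger.info("read %d records (qual > %g) from %d samples", n_read, config.min_qual, len(records_raw))

    records = {
        s: _io.apply_caller_thresholds(
            v, min_alt=config.min_alt, min_depth=config.min_depth, min_vaf=config.min_vaf
        )
        for s, v in records_raw.items()
    }
    n_kept = sum(len(v) for v in records.values())
    report["stages"]["records_after_caller_thresholds"] = n_kept
    logger.info("caller thresholds kept %d/%d records", n_kept, n_read)

    site_set = _io.union_sites(records)
    report["stages"]["sites_in_union"] = len(site_set)
    if config.bed is not None:
        site_set = _io.restrict_to_intervals(site_set, config.bed)
        report["stages"]["sites_after_cds_restriction"] = len(site_set)
        records = {
            s: [r for r in v if r.site_key in site_set] for s, v in records.items()
        }
    logger.info("site union: %d sites", len(site_set))

    depth_table = _io.read_depth_table(depth_path, site_set, list(records))
    vmat = _distance.build_vaf_matrix(records, depth_table, site_set, uncalled=config.uncalled)
    dm = _distance.pairwise_distance(vmat, min_pair_depth=config.min_pair_depth)
    nij = dm.n_sites_used[~np.eye(len(dm.samples), dtype=bool)]
    report["stages"]["pair_sites_min"] = int(nij.min())
    report["stages"]["pair_sites_median"] = float(np.median(nij))
    report["stages"]["pair_sites_max"] = int(nij.max())

    _distance.write_distance_tsv(dm, outdir / "distance.tsv")
    tree = _hierarchy.ward_cluster(dm)
    (outdir / "tree.nwk").write_text(_hierarchy.to_newick(tree) + "\n")
    report["stages"]["dendrogram_leaves"] = len(tree.leaves)

    boot = _hierarchy.bootstrap_support(
        vmat,
        B=config.bootstrap_B,
        min_pair_depth=config.min_pair_depth,
        seed=config.seed,
        reference=tree,
    )
    with (outdir / "support.tsv").open("w") as fh:
        fh.write("clade\tsupport\tn_replicates\n")
        for clade, frac in boot.table():
            fh.write(f"{clade}\t{frac:.6f}\t{boot.n_replicates}\n")
    report["stages"]["bootstrap_replicates"] = boot.n_replicates
    report["stages"]["bootstrap_dropped"] = boot.n_dropped

    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("wrote results to %s", outdir)
    return {
        "report": report,
        "distance": dm,
        "tree": tree,
        "bootstrap": boot,
        "vaf_matrix": vmat,
        "manifest": manifest,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# hybrid intermediacy instrumentation
# ---------------------------------------------------------------------------


def hybrid_intermediacy(
    dm: _distance.DistanceMatrix, labels: dict[str, str]
) -> dict[str, dict]:
    """Check that each F1 hybrid group sits between its parent clusters.

    For a hybrid labelled ``spAAxspBB_F1``, the mean distance from its
    samples to each parent group must be smaller than the mean distance
    between the two parent groups.  Returns per-hybrid-group diagnostics.
    """
    samples = dm.samples
    idx = {s: i for i, s in enumerate(samples)}
    groups: dict[str, list[int]] = {}
    for s in samples:
        groups.setdefault(labels[s], []).append(idx[s])

    def mean_between(a: list[int], b: list[int]) -> float:
        vals = [dm.d[i, j] for i in a for j in b if i != j]
        return float(np.mean(vals))

    out: dict[str, dict] = {}
    for lab, members in groups.items():
        if "x" not in lab or not lab.endswith("_F1"):
            continue
        pa, pb = lab[: -len("_F1")].split("x")
        if pa not in groups or pb not in groups:
            continue
        d_ha = mean_between(members, groups[pa])
        d_hb = mean_between(members, groups[pb])
        d_ab = mean_between(groups[pa], groups[pb])
        out[lab] = {
            "to_parent_a": d_ha,
            "to_parent_b": d_hb,
            "between_parents": d_ab,
            "intermediate": bool(d_ha < d_ab and d_hb < d_ab),
        }
    return out


# ---------------------------------------------------------------------------
# flat key=value config files (CLI flags override file values)
# ---------------------------------------------------------------------------

_INT_KEYS = {"min_alt", "min_depth", "min_pair_depth", "bootstrap_B", "seed"}
_FLOAT_KEYS = {"min_qual", "min_vaf", "mapping_q", "base_q"}


def load_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file into a dict of overrides."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _INT_KEYS:
            out[key] = int(value)
        elif key in _FLOAT_KEYS:
            out[key] = float(value)
        else:
            out[key] = value
    return out
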