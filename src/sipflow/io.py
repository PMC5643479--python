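"""Readers, writers, configuration and pipeline orchestration.

All tables are plain text: fraction tables as CSV, count tables as TSV
with a trailing QIIME-style ``taxonomy`` column (BIOM v1 JSON is also
accepted on read), results as TSV.  Output files carry ``##`` comment
headers with the config hash and seed so every run is reproducible from
its inputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import activity as _activity
from . import gradient as _gradient
from . import isotope as _isotope
from . import metagenome as _metagenome
from . import simulate as _simulate
from .activity import CountTable
from .gradient import DensityWindow, GradientProfile, PoolingScheme
from .isotope import CalibrationAnchor
from .simulate import SimulationConfig, TaxonSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_fraction_table",
    "write_fraction_table",
    "read_count_table",
    "write_count_table",
    "read_biom_table",
    "read_ko_list",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


# ---------------------------------------------------------------- fraction CSV

FRACTION_COLUMNS = ["fraction_index", "density_g_ml", "dna_ng", "copies_16s"]


def write_fraction_table(profile: GradientProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_fraction_table(path: str | Path, **meta: str) -> GradientProfile:
    """Read a fraction-table CSV into a gradient profile.

    Densities are validated against the physical range; tables supplied
    top-first are re-indexed bottom-first with a logged warning.
    """
    frame = pd.read_csv(path, comment="#")
    return GradientProfile.from_frame(frame, **meta)


# ---------------------------------------------------------------- count tables

TAXON_COLUMN = "#OTU ID"


def write_count_table(
    table: CountTable, path: str | Path, comments: Sequence[str] = ()
) -> None:
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy", table.lineages)
    buf = _io.StringIO()
    for line in comments:
        buf.write(f"## {line}\n")
    out.index.name = TAXON_COLUMN
    out.to_csv(buf, sep="\t", lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (taxon id column, sample columns, trailing
    ``taxonomy`` lineage column).  Counts must be non-negative integers;
    a violation is reported with its row."""
    text = Path(path).read_text().splitlines()
    rows = [line for line in text if line.strip() and not line.startswith("##")]
    frame = pd.read_csv(_io.StringIO("\n".join(rows)), sep="\t", dtype=str)
    if frame.columns[0] not in (TAXON_COLUMN, "taxon", "taxon_id"):
        raise ValueError(
            f"first column must be the taxon id ({TAXON_COLUMN!r}), got {frame.columns[0]!r}"
        )
    frame = frame.set_index(frame.columns[0])
    if "taxonomy" in frame.columns:
        lineages = frame.pop("taxonomy").fillna("")
    else:
        lineages = None
    counts = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="raise")
        bad = values[values < 0]
        if len(bad):
            raise ValueError(
                f"negative count in column {col!r}, row {bad.index[0]!r}: {bad.iloc[0]}"
            )
        counts[col] = values
    return CountTable(counts, lineages)


def read_biom_table(path: str | Path) -> CountTable:
    """Read a BIOM v1 (JSON) OTU table, dense or sparse."""
    doc = json.loads(Path(path).read_text())
    n_rows, n_cols = doc["shape"]
    counts = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        counts = np.asarray(doc["data"], dtype=float)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    lineages = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy", "")
        lineages[r["id"]] = "; ".join(tax) if isinstance(tax, (list, tuple)) else tax
    frame = pd.DataFrame(counts, index=taxa, columns=samples)
    return CountTable(frame, pd.Series(lineages))


def read_ko_list(path: str | Path) -> list[str]:
    """One KO identifier per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_copy_numbers(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(
        frame.iloc[:, 1].to_numpy(float), index=frame.iloc[:, 0], name="copy_number"
    )


def read_ko_reference(path: str | Path) -> pd.DataFrame:
    """Taxon x KO gene-count table (first column taxon id)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame.set_index(frame.columns[0]).astype(float)


# ------------------------------------------------------------------ run config


@dataclass
class RunConfig:
    substrate: str = "cellulose"
    life_stage: str = "larva"
    rank: str = "family"
    alpha: float = 0.05
    tier_on: str = "q"
    fdr_within_pool: bool = True
    seed: int = 0
    output_dir: str = "sipflow_out"
    log_level: str = "INFO"
    pooling: PoolingScheme | None = None
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    ko: dict[str, Any] | None = None
    irms: dict[str, Any] | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.substrate not in ("cellulose", "urea"):
            raise ConfigError(f"substrate: must be 'cellulose' or 'urea', got {self.substrate!r}")
        if self.rank not in _activity.RANKS:
            raise ConfigError(f"rank: unknown rank {self.rank!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha: must be in (0,1), got {self.alpha}")
        if self.tier_on not in ("p", "q"):
            raise ConfigError(f"tier_on: must be 'p' or 'q', got {self.tier_on!r}")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("one of 'simulate' or 'inputs' must be configured")
        if self.inputs is not None:
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigError(f"inputs.{key}: file not found: {path}")

    def config_hash(self) -> str:
        # output location and verbosity do not affect results
        substantive = {
            k: v for k, v in self.raw.items() if k not in ("output_dir", "log_level")
        }
        blob = json.dumps(substantive, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _parse_pooling(block: Any) -> PoolingScheme:
    try:
        windows = [
            DensityWindow(
                name=w["name"],
                low=float(w["low"]),
                high=float(w["high"]),
                dense=bool(w.get("dense", False)),
            )
            for w in block["windows"]
        ]
        return PoolingScheme(windows)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"pooling: malformed window block ({exc})") from exc


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    known = {
        "substrate", "life_stage", "rank", "alpha", "tier_on", "fdr_within_pool",
        "seed", "output_dir", "log_level", "pooling", "simulate", "inputs",
        "ko", "irms",
    }
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {k: doc[k] for k in known & set(doc)}
    if "pooling" in kwargs and kwargs["pooling"] is not None:
        kwargs["pooling"] = _parse_pooling(kwargs["pooling"])
    return RunConfig(raw=doc, **kwargs)


def build_simulation_config(cfg: RunConfig) -> SimulationConfig:
    block = dict(cfg.simulate or {})
    community_keys = {"n_taxa", "n_labeled", "atom_excess", "gc_range", "copy_number_range"}
    community = {k: block.pop(k) for k in list(block) if k in community_keys}
    if "gc_range" in community:
        community["gc_range"] = tuple(community["gc_range"])
    if "copy_number_range" in community:
        community["copy_number_range"] = tuple(community["copy_number_range"])
    taxa = _simulate.default_community(seed=cfg.seed, **community)
    block.setdefault("isotope", "13C" if cfg.substrate == "cellulose" else "15N")
    block.setdefault("n_fractions", 12 if cfg.substrate == "cellulose" else 24)
    try:
        return SimulationConfig(
            taxa=taxa, pooling=cfg.pooling, seed=cfg.seed, **block
        )
    except TypeError as exc:
        raise ConfigError(f"simulate: {exc}") from exc


# -------------------------------------------------------------------- pipeline


def _write_tsv(frame: pd.DataFrame, path: Path, stamp: Sequence[str]) -> None:
    buf = _io.StringIO()
    for line in stamp:
        buf.write(f"## {line}\n")
    frame.to_csv(buf, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
    path.write_text(buf.getvalue())


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis: (simulate) -> normalize -> pool ->
    activity -> optional KO enrichment -> optional IRMS comparison.

    Writes a result bundle under ``cfg.output_dir`` and returns the
    in-memory results.  Identical config + seed give identical bundles.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = [f"sipflow config_hash={cfg.config_hash()} seed={cfg.seed}"]
    bundle: dict[str, Any] = {}

    if cfg.simulate is not None:
        sim_config = build_simulation_config(cfg)
        dataset = _simulate.simulate_dataset(sim_config)
        labeled_profile, control_profile = (
            dataset.labeled_profile, dataset.control_profile,
        )
        labeled_counts, control_counts = dataset.labeled_counts, dataset.control_counts
        scheme = dataset.pooling
        truth = dataset.truth
        write_fraction_table(labeled_profile, outdir / "labeled_fractions.csv")
        write_fraction_table(control_profile, outdir / "control_fractions.csv")
        write_count_table(labeled_counts, outdir / "labeled_counts.tsv", stamp)
        write_count_table(control_counts, outdir / "control_counts.tsv", stamp)
        truth.reset_index().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        bundle["truth"] = truth
    else:
        inputs = cfg.inputs or {}
        for key in ("labeled_counts", "control_counts"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key}: required when not simulating")
        reader = lambda p: (
            read_biom_table(p) if str(p).endswith(".biom") else read_count_table(p)
        )
        labeled_counts = reader(inputs["labeled_counts"])
        control_counts = reader(inputs["control_counts"])
        labeled_profile = control_profile = None
        if "labeled_fractions" in inputs and "control_fractions" in inputs:
            labeled_profile = read_fraction_table(
                inputs["labeled_fractions"], substrate=cfg.substrate, treatment="labeled"
            )
            control_profile = read_fraction_table(
                inputs["control_fractions"], substrate=cfg.substrate, treatment="control"
            )
        scheme = cfg.pooling or _gradient.default_scheme(cfg.substrate)
        truth = None

    # gradient QC: percent-of-gradient normalization, pooling, density shift
    if labeled_profile is not None:
        qc_rows = []
        for profile in (labeled_profile, control_profile):
            pooled, unpooled = _gradient.pool_fractions(profile, scheme)
            for p in pooled:
                qc_rows.append(
                    {
                        "treatment": profile.treatment,
                        "pool": p.name,
                        "dense": p.dense,
                        "n_fractions": len(p.member_indices),
                        "dna_percent": p.dna_percent,
                        "copies_percent": p.copies_percent,
                    }
                )
            logger.info(
                "%s gradient: %.2f%% of DNA unpooled", profile.treatment,
                unpooled["dna_percent"].sum() if len(unpooled) else 0.0,
            )
        qc = pd.DataFrame(qc_rows)
        shift = _gradient.density_shift(labeled_profile, control_profile)
        bundle["gradient_qc"] = qc
        bundle["density_shift"] = shift
        _write_tsv(qc, outdir / "gradient_qc.tsv", stamp + [f"density_shift_g_ml={shift:.6f}"])
        logger.info("density shift (labeled - control): %+.5f g/ml", shift)

    # activity at the configured rank
    labeled_rank = _activity.collapse_rank(labeled_counts, cfg.rank)
    control_rank = _activity.collapse_rank(control_counts, cfg.rank)
    records = _activity.compute_activity(
        labeled_rank,
        control_rank,
        dense_pools=scheme.dense_names,
        tier_on=cfg.tier_on,
        fdr_within_pool=cfg.fdr_within_pool,
    )
    bundle["activity"] = records
    _write_tsv(records, outdir / "activity.tsv", stamp)
    matrix, annot = _activity.activity_heatmap_matrix(records)
    matrix.to_csv(outdir / "activity_matrix.tsv", sep="\t", float_format="%.6f")
    annot.to_csv(outdir / "activity_annotations.tsv", sep="\t")
    ranked = _activity.rank_by_activity(records)
    _write_tsv(ranked, outdir / "ranked_taxa.tsv", stamp)
    bundle["ranked"] = ranked
    n_sig = int(((records["q"] < cfg.alpha) & (records["A"] > 0)).sum())
    logger.info(
        "%d of %d (taxon, pool) tests significantly enriched at q<%g",
        n_sig, len(records), cfg.alpha,
    )

    if truth is not None:
        otu_records = _activity.compute_activity(
            labeled_counts, control_counts, dense_pools=scheme.dense_names,
            tier_on=cfg.tier_on, fdr_within_pool=cfg.fdr_within_pool,
        )
        detection = _simulate.evaluate_detection(otu_records, truth, alpha=cfg.alpha)
        bundle["detection"] = detection
        _write_tsv(
            pd.DataFrame([detection]), outdir / "detection.tsv", stamp
        )

    # optional KO-profile enrichment
    if cfg.ko is not None:
        ko_cfg = cfg.ko
        copy_numbers = read_copy_numbers(ko_cfg["copy_numbers"])
        ko_ref = read_ko_reference(ko_cfg["gene_counts"])
        ko_subset = read_ko_list(ko_cfg["ko_list"]) if "ko_list" in ko_cfg else None
        labeled_families = ko_cfg.get("labeled_taxa")
        lab_table, ctl_table = labeled_counts, control_counts
        if labeled_families:
            lab_table, _ = _metagenome.filter_to_labeled_taxa(
                lab_table, labeled_families, rank=ko_cfg.get("filter_rank", "family")
            )
            ctl_table, _ = _metagenome.filter_to_labeled_taxa(
                ctl_table, labeled_families, rank=ko_cfg.get("filter_rank", "family")
            )
        default_cn = ko_cfg.get("default_copy_number")
        lab_corr = _metagenome.copy_number_normalize(lab_table, copy_numbers, default_cn)
        ctl_corr = _metagenome.copy_number_normalize(ctl_table, copy_numbers, default_cn)
        lab_ko = _metagenome.predict_ko_profile(lab_corr, ko_ref)
        ctl_ko = _metagenome.predict_ko_profile(ctl_corr, ko_ref)
        enrichment = _metagenome.ko_enrichment(
            lab_ko, ctl_ko, dense_pools=scheme.dense_names, ko_subset=ko_subset
        )
        bundle["ko_enrichment"] = enrichment
        _write_tsv(enrichment, outdir / "ko_enrichment.tsv", stamp)
        _metagenome.ko_heatmap_matrix(enrichment).to_csv(
            outdir / "ko_matrix.tsv", sep="\t", float_format="%.6f"
        )

    # optional IRMS comparison
    if cfg.irms is not None:
        irms_cfg = cfg.irms
        measurements = pd.read_csv(irms_cfg["measurements"], comment="#")
        anchors = [
            CalibrationAnchor(a["name"], float(a["certified"]), float(a["measured"]))
            for a in irms_cfg.get("anchors", [])
        ]
        if anchors:
            cal = _isotope.two_point_calibration(anchors[0], anchors[1])
            measurements = measurements.assign(
                delta_per_mil=cal(measurements["delta_per_mil"])
            )
        per_bio = _isotope.aggregate_technical(measurements)
        rows = []
        for (tissue, stage), grp in per_bio.groupby(["tissue", "life_stage"]):
            g15 = grp.loc[grp["treatment"] == "15N", "delta_per_mil"]
            g14 = grp.loc[grp["treatment"] == "14N", "delta_per_mil"]
            if len(g15) < 2 or len(g14) < 2:
                continue
            res = _isotope.compare_treatments(g15, g14, alpha=cfg.alpha)
            rows.append({"tissue": tissue, "life_stage": stage, **res})
        irms_out = pd.DataFrame(rows)
        bundle["irms"] = irms_out
        _write_tsv(irms_out, outdir / "irms_comparison.tsv", stamp)

    return bundle
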