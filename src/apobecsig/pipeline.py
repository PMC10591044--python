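"""End-to-end orchestration: simulate/load -> filter -> spectra -> enrichment
-> signature refit (and optional de novo extraction) -> topography -> cohort
statistics, with a single validated configuration and a reproducible report.

The pipeline is a composition of the library stages; everything it writes
is plain text (per-stage TSVs plus one JSON report), and an identical
configuration and seed reproduce every output byte.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import Reference, FastaReference
from .variants import SomaticVariant
from . import variant_io, spectrum, enrichment, signatures as sigs, topography, cohort_stats
from .synthetic_data import CohortSimulation, TimingTrack, simulate_cohort


class ConfigError(ValueError):
    """Configuration validation failure carrying the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


_KNOWN_KEYS = {
    "sample_sheet", "reference_fasta", "timing_track", "signature_tsv",
    "outdir", "seed", "min_alt_reads", "min_total_reads", "min_vaf",
    "q_threshold", "flank", "prune_threshold", "denovo_rank",
    "denovo_restarts", "excluded_contigs", "early_is_high", "simulate",
    "log_level",
}
_SIMULATE_KEYS = {
    "n_tumors", "n_controls", "n_sbs", "contig_lengths", "gc_fraction",
    "contaminant_fraction", "indel_base", "indel_per_es", "sv_base", "sv_per_es",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with the study defaults filled in."""

    outdir: str
    seed: int = 0
    sample_sheet: str | None = None
    reference_fasta: str | None = None
    timing_track: str | None = None
    signature_tsv: str | None = None
    simulate: dict | None = None
    min_alt_reads: int = 3
    min_total_reads: int = 10
    min_vaf: float = 0.05
    q_threshold: float = 0.1
    flank: int = 20
    prune_threshold: float = 0.06
    denovo_rank: int | None = None
    denovo_restarts: int = 10
    excluded_contigs: tuple[str, ...] = ("chrM",)
    early_is_high: bool = True
    log_level: str = "info"


def validate_config(raw: dict) -> RunConfig:
    """Validate a config mapping, reporting *all* errors at once."""
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    if "outdir" not in raw:
        errors.append("outdir is required")
    sim = raw.get("simulate")
    if sim is not None:
        bad = set(sim) - _SIMULATE_KEYS
        if bad:
            errors.append(f"unknown simulate keys: {sorted(bad)}")
    else:
        if not raw.get("sample_sheet"):
            errors.append("either simulate: or sample_sheet: must be given")
        if not raw.get("reference_fasta"):
            errors.append("reference_fasta is required without simulate:")
    for key, lo, hi in (("min_vaf", 0.0, 1.0), ("q_threshold", 0.0, 1.0),
                        ("prune_threshold", 0.0, 1.0)):
        if key in raw and not (lo <= float(raw[key]) < hi):
            errors.append(f"{key} must lie in [{lo}, {hi}), got {raw[key]}")
    for key in ("min_alt_reads", "min_total_reads", "flank", "seed"):
        if key in raw and int(raw[key]) < 0:
            errors.append(f"{key} must be nonnegative, got {raw[key]}")
    for key in ("sample_sheet", "reference_fasta", "timing_track", "signature_tsv"):
        path = raw.get(key)
        if path and not Path(path).exists():
            errors.append(f"{key} points at a missing file: {path}")
    if errors:
        raise ConfigError(errors)
    known = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    if "excluded_contigs" in known:
        known["excluded_contigs"] = tuple(known["excluded_contigs"])
    return RunConfig(**known)


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config file must hold a mapping"])
    return validate_config(raw)


@dataclass
class CohortInputs:
    """Per-sample variant sets plus shared reference data, however obtained."""

    reference: Reference
    sbs_by_sample: dict[str, list[SomaticVariant]]
    indels_by_sample: dict[str, list[SomaticVariant]]
    sv_by_sample: dict[str, list[spectrum.SvRecord]]
    groups: dict[str, str]
    timing: list[tuple[str, int, int, float]] | None = None


@dataclass
class CohortReport:
    per_sample: pd.DataFrame
    quintile_counts: dict[str, list[int]] = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    denovo: dict | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "per_sample": json.loads(self.per_sample.to_json(orient="index")),
            "quintile_counts": self.quintile_counts,
            "comparisons": self.comparisons,
            "denovo": self.denovo,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _log(config: RunConfig, message: str) -> None:
    if config.log_level != "quiet":
        print(f"[apobec-sigscan] {message}", file=sys.stderr)


def inputs_from_simulation(sim: CohortSimulation) -> CohortInputs:
    track = [(c, s, e, v) for c, s, e, v in sim.timing_track.intervals]
    return CohortInputs(
        reference=sim.genome,
        sbs_by_sample={s.sample_id: list(s.sbs_variants) for s in sim.samples},
        indels_by_sample={s.sample_id: list(s.indel_variants) for s in sim.samples},
        sv_by_sample={s.sample_id: list(s.sv_records) for s in sim.samples},
        groups={s.sample_id: ("CAG-A3B" if s.group == "tumor" else "WT")
                for s in sim.samples},
        timing=track,
    )


def inputs_from_files(config: RunConfig) -> CohortInputs:
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    required = {"sample_id", "vcf"}
    if not required <= set(sheet.columns):
        raise ConfigError([f"sample sheet needs columns {sorted(required)}"])
    reference = FastaReference(config.reference_fasta)
    sbs, indels, svs, groups = {}, {}, {}, {}
    for _, row in sheet.iterrows():
        sid = str(row["sample_id"])
        calls = variant_io.read_somatic_vcf(row["vcf"], sample_id=None)
        for v in calls:
            v.sample_id = sid
        sbs[sid] = [v for v in calls if v.variant_class.name in ("SBS", "MNV")]
        indels[sid] = [v for v in calls if v.variant_class.name in ("INS", "DEL")]
        svs[sid] = (variant_io.read_sv_vcf(row["sv_vcf"], sid)
                    if "sv_vcf" in sheet.columns and pd.notna(row.get("sv_vcf")) else [])
        groups[sid] = str(row["group"]) if "group" in sheet.columns else "cohort"
    timing = None
    if config.timing_track:
        rows = pd.read_csv(config.timing_track, sep="\t", header=None,
                           names=["contig", "start", "end", "value"])
        timing = [tuple(r) for r in rows.itertuples(index=False)]
    return CohortInputs(reference, sbs, indels, svs, groups, timing)


def analyze_cohort(inputs: CohortInputs, config: RunConfig,
                   reference_signatures: sigs.SignatureSet | None = None) -> CohortReport:
    """Run every analysis stage over already-loaded cohort inputs."""
    refs = reference_signatures or (
        sigs.read_signature_tsv(config.signature_tsv) if config.signature_tsv
        else sigs.synthetic_reference_signatures()
    )
    policy = variant_io.FilterPolicy(
        min_alt_reads=config.min_alt_reads,
        min_total_reads=config.min_total_reads,
        min_vaf_exclusive=config.min_vaf,
        excluded_contigs=frozenset(),  # chrM excluded at the enrichment stage
    )
    reference = inputs.reference
    enrich_index = enrichment.EnrichmentContextIndex(reference)
    quintiles = (topography.assign_timing_quintiles(inputs.timing, config.early_is_high)
                 if inputs.timing else None)

    rows = []
    catalogs: list[spectrum.SbsCatalog] = []
    enrich_input: dict[str, list[SomaticVariant]] = {}
    per_sample_quintiles: dict[str, list[int]] = {}
    for sid in sorted(inputs.sbs_by_sample):
        _log(config, f"sample {sid}: filtering and building spectra")
        sbs_kept = variant_io.apply_quality_filters(inputs.sbs_by_sample[sid], policy).kept
        indel_kept = variant_io.apply_quality_filters(
            inputs.indels_by_sample.get(sid, []), policy).kept
        catalog = spectrum.build_sbs_catalog(sbs_kept, reference, sid)
        catalogs.append(catalog)
        exposure = sigs.refit_exposures(catalog, refs, config.prune_threshold)
        indel_catalog = spectrum.build_indel_catalog(indel_kept, reference, sid)
        sv_tally = spectrum.tally_structural_variants(
            inputs.sv_by_sample.get(sid, []), sid)
        informative = variant_io.exclude_for_enrichment(sbs_kept, reference)
        enrich_input[sid] = informative
        clusters = topography.cluster_class_counts(
            topography.detect_clusters(sbs_kept))
        row = {
            "sample_id": sid,
            "group": inputs.groups.get(sid, "cohort"),
            "sbs_total": catalog.total,
            "pct_sbs2": sigs.sbs2_percentage(exposure),
            "unexplained": exposure.unexplained,
            "indel_total_lt200": indel_catalog.total,
            "sv_total": sv_tally.total,
            "n_dispersed": clusters["dispersed"],
            "n_omikli": clusters["omikli"],
            "n_kataegis": clusters["kataegis"],
        }
        for cat in spectrum.INDEL_CATEGORIES:
            row[f"indel_{cat}"] = indel_catalog.counts[cat]
        if quintiles is not None:
            qc = topography.mutations_per_quintile(sbs_kept, quintiles)
            per_sample_quintiles[sid] = [int(c) for c in qc.counts]
        rows.append(row)

    _log(config, "scoring TCW enrichment across the cohort")
    results = enrichment.evaluate_cohort(
        enrich_input, reference, flank=config.flank,
        q_threshold=config.q_threshold, index=enrich_index)
    by_id = {r.sample_id: r for r in results}
    for row in rows:
        r = by_id[row["sample_id"]]
        row.update(enrichment_score=r.score, enrichment_p=r.p_value,
                   enrichment_q=r.q_value, stratum=r.stratum)

    table = pd.DataFrame(rows).set_index("sample_id")

    comparisons: dict = {}
    sv_comp = cohort_stats.es_stratified_sv_comparison(table, control_group="WT")
    comparisons["sv_by_stratum"] = {
        "medians": sv_comp.medians,
        "pairwise_p": {f"{a}|{b}": p for (a, b), p in sv_comp.pairwise_p.items()},
        "skipped": sv_comp.skipped,
    }
    try:
        corr = cohort_stats.correlate(table["enrichment_score"],
                                      table["indel_total_lt200"], "spearman")
        comparisons["es_vs_indels"] = {"rho": corr.coefficient, "p": corr.p_value}
    except ValueError:
        comparisons["es_vs_indels"] = None
    try:
        corr = cohort_stats.correlate(table["enrichment_score"], table["pct_sbs2"])
        comparisons["es_vs_pct_sbs2"] = {"r": corr.coefficient, "p": corr.p_value,
                                         "slope": corr.slope}
    except ValueError:
        comparisons["es_vs_pct_sbs2"] = None

    denovo = None
    if config.denovo_rank:
        _log(config, f"extracting {config.denovo_rank} de novo signatures")
        matrix = spectrum.catalogs_to_frame(catalogs).to_numpy()
        extracted, exposures = sigs.extract_denovo(
            matrix, config.denovo_rank, n_restarts=config.denovo_restarts,
            seed=config.seed)
        matches = sigs.match_to_reference(extracted, refs)
        denovo = {
            "signatures": {n: extracted.matrix[:, i].tolist()
                           for i, n in enumerate(extracted.names)},
            "matches": {n: {"reference": m[0], "cosine": m[1]}
                        for n, m in matches.items()},
        }

    report = CohortReport(
        per_sample=table,
        quintile_counts=per_sample_quintiles,
        comparisons=comparisons,
        denovo=denovo,
        metadata={
            "seed": config.seed,
            "thresholds": {
                "min_alt_reads": config.min_alt_reads,
                "min_total_reads": config.min_total_reads,
                "min_vaf_exclusive": config.min_vaf,
                "q_threshold": config.q_threshold,
                "flank": config.flank,
                "prune_threshold": config.prune_threshold,
            },
            "n_samples": len(rows),
        },
    )
    return report


def run_pipeline(config: RunConfig) -> CohortReport:
    """Execute the full pipeline per the configuration and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        _log(config, "simulating synthetic cohort")
        sim = simulate_cohort(seed=config.seed, **{
            k: (tuple(v) if k == "contig_lengths" else v)
            for k, v in config.simulate.items()
        })
        inputs = inputs_from_simulation(sim)
    else:
        inputs = inputs_from_files(config)
    report = analyze_cohort(inputs, config)
    report.per_sample.to_csv(outdir / "per_sample.tsv", sep="\t")
    (outdir / "report.json").write_text(report.to_json())
    _log(config, f"report written to {outdir / 'report.json'}")
    return report
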