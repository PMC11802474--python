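"""Aggregation of all module outputs into one serialisable report.

A single streaming pass over the input feeds every applicable module;
the resulting :class:`QCReport` serialises to JSON with a stable key
order and a schema version (the MultiQC-consumable interface) and to a
self-contained HTML file.  Given identical inputs and configuration the
JSON is byte-identical (timestamps excluded from the determinism
contract).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

from . import __version__
from .adapter_probes import ProbeHits, build_matcher, default_probe_set
from .config import QCConfig
from .duplication import DupSketch, fingerprint
from .io_formats import open_records, pair_reads
from .overrepresented import (
    ContaminantDB,
    FragmentTable,
    build_contaminant_index,
    bundled_contaminant_db,
    flag_overrepresented,
    identify_fragment,
)
from .pair_overlap import InsertSizeHistogram, find_overlap
from .platform_metrics import OntActivity, TileQuality, parse_ont_meta
from .qc_metrics import PositionProfile, ReadSummaries, accumulate

SCHEMA_VERSION = "1.0"


@dataclass
class QCReport:
    metadata: dict
    summary: dict
    per_position: dict
    per_read: dict
    adapter_content: dict
    insert_size: dict | None
    duplication: dict
    overrepresented: dict
    per_tile: dict | None
    ont: dict | None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "metadata": self.metadata,
            "summary": self.summary,
            "per_position": self.per_position,
            "per_read": self.per_read,
            "adapter_content": self.adapter_content,
            "insert_size": self.insert_size,
            "duplication": self.duplication,
            "overrepresented": self.overrepresented,
            "per_tile": self.per_tile,
            "ont": self.ont,
            "warnings": self.warnings,
        }


class _Accumulators:
    """All per-read state for one streaming pass."""

    def __init__(self, cfg: QCConfig, db: ContaminantDB | None, probes=None):
        self.cfg = cfg
        self.profile = PositionProfile()
        self.summaries = ReadSummaries()
        probes = probes or default_probe_set("auto", cfg.probe_len)
        self.matcher = build_matcher(probes, cfg.probe_len)
        self.probe_hits = ProbeHits(probes)
        self.sketch = DupSketch(cfg.sketch_capacity)
        self.fragments = FragmentTable(cfg)
        self.tiles = TileQuality()
        self.ont = OntActivity()
        self.db = db
        self.read_index = 0
        self.total_bases = 0

    def add(self, record) -> None:
        accumulate(record, self.profile, self.summaries)
        self.probe_hits.add(self.matcher.scan(record.sequence))
        self.sketch.insert(fingerprint(record, self.cfg))
        self.fragments.add_read(record, self.read_index)
        self.tiles.add(record)
        meta, warns = parse_ont_meta(record)
        self.ont.warnings.extend(warns)
        self.ont.add(record, meta)
        self.total_bases += len(record)
        self.read_index += 1


def run_qc(
    inputs,
    cfg: QCConfig | None = None,
    contaminants=None,
    records=None,
    pairs=None,
    probe_file=None,
) -> QCReport:
    """One streaming QC pass.

    Parameters
    ----------
    inputs:
        One path (FASTQ/FASTQ.gz/uBAM) or two (paired FASTQ).  Already
        parsed streams can be supplied instead via *records* / *pairs*
        (the paths are then used only for the report metadata).
    cfg:
        :class:`QCConfig`; defaults apply when omitted.
    contaminants:
        Path to a UniVec-style FASTA; the bundled mini-database is used
        when omitted.
    """
    cfg = cfg or QCConfig()
    inputs = [str(p) for p in (inputs if isinstance(inputs, (list, tuple)) else [inputs])]
    if len(inputs) > 2:
        raise ValueError("expected one input file or a paired-end duo")
    db = (
        build_contaminant_index(contaminants, cfg)
        if contaminants is not None
        else bundled_contaminant_db(cfg)
    )
    probes = None
    if probe_file is not None:
        from .adapter_probes import load_probe_file

        probes = [p for _, p in load_probe_file(probe_file, cfg.probe_len)]
    acc = _Accumulators(cfg, db, probes)
    insert_hist: InsertSizeHistogram | None = None

    paired = pairs is not None or len(inputs) == 2
    if paired:
        if pairs is None:
            pairs = pair_reads(open_records(inputs[0]), open_records(inputs[1]))
        insert_hist = InsertSizeHistogram()
        for pair in pairs:
            acc.add(pair.r1)
            acc.add(pair.r2)
            insert_hist.add(find_overlap(pair, cfg))
    else:
        if records is None:
            records = open_records(inputs[0])
        for record in records:
            acc.add(record)
    return _build_report(inputs, cfg, acc, insert_hist)


def _build_report(
    inputs, cfg: QCConfig, acc: _Accumulators, insert_hist
) -> QCReport:
    summaries, profile = acc.summaries, acc.profile
    n = summaries.total_reads

    overrep_rows = []
    if acc.fragments.sampled_reads:
        for frag, count, fraction in flag_overrepresented(acc.fragments, cfg):
            hit = (
                identify_fragment(frag, acc.db, cfg)
                if len(frag) >= cfg.kmer_size
                else None
            )
            overrep_rows.append(
                {
                    "sequence": frag,
                    "count": count,
                    "fraction": fraction,
                    "best_match_id": hit.target_id if hit else None,
                    "identity": round(hit.identity, 6) if hit else None,
                }
            )

    dup = acc.sketch.estimate() if n else None
    mean_len = acc.total_bases / n if n else 0.0

    tile_counts = dict(sorted(acc.tiles.counts.items()))
    tile_section = (
        {
            "reads_with_tile": acc.tiles.reads_with_tile,
            "counts": {str(t): c for t, c in tile_counts.items()},
            "mean_quality": {
                str(t): round(q, 4) for t, q in sorted(acc.tiles.mean_quality().items())
            },
        }
        if acc.tiles.reads_with_tile
        else None
    )
    ont_section = None
    if acc.ont.reads_with_channel or acc.ont.speeds:
        ont_section = {
            "reads_with_channel": acc.ont.reads_with_channel,
            "channel_activity": {
                str(ch): {"reads": r, "bases": b}
                for ch, (r, b) in acc.ont.channel_activity().items()
            },
            "translocation_speed": acc.ont.speed_summary(),
            "speed_time_series": acc.ont.speed_time_series(),
        }

    report = QCReport(
        metadata={
            "tool": "seqscope",
            "version": __version__,
            "inputs": list(inputs),
            "config": cfg.to_dict(),
        },
        summary={
            "total_reads": n,
            "total_bases": acc.total_bases,
            "mean_length": round(mean_len, 4),
            "reads_q15_expected_error": summaries.reads_at_least(15),
            "reads_q20_expected_error": summaries.reads_at_least(20),
            "reads_q20_arithmetic": summaries.reads_at_least(20, "arithmetic"),
            "reads_q30_arithmetic": summaries.reads_at_least(30, "arithmetic"),
        },
        per_position={
            "bin_starts": [int(x) for x in profile.binner.starts()[: profile.max_bin + 1]],
            "coverage": [int(x) for x in profile.coverage],
            "base_fractions": _round_matrix(profile.base_fractions()),
            "mean_phred": _round_vector(profile.mean_phred()),
            "phred_of_mean_error": _round_vector(profile.phred_of_mean_error()),
        }
        if n
        else {"bin_starts": [], "coverage": [], "base_fractions": [],
              "mean_phred": [], "phred_of_mean_error": []},
        per_read={
            "length_hist": {str(k): v for k, v in sorted(summaries.length_hist.items())},
            "gc_hist": summaries.gc_hist.tolist(),
            "gc_undefined": summaries.gc_undefined,
            "q_hist_expected_error": summaries.q_hist_expected_error.tolist(),
            "q_hist_arithmetic": summaries.q_hist_arithmetic.tolist(),
            "empty_reads": summaries.empty_reads,
        },
        adapter_content={
            "total_reads": acc.probe_hits.total_reads,
            "probes": {
                label: {
                    "reads_with_hit": acc.probe_hits.reads_with_hit[label],
                    "fraction": (
                        acc.probe_hits.hit_fraction(label)
                    ),
                    "first_hit_positions": {
                        str(acc.probe_hits.binner.bin_start(b)): c
                        for b, c in sorted(acc.probe_hits.first_hit_bins[label].items())
                    },
                }
                for label in acc.probe_hits.labels
            },
        },
        insert_size=(
            {
                "histogram": {str(k): v for k, v in sorted(insert_hist.counts.items())},
                "undetermined": insert_hist.undetermined,
                "total_pairs": insert_hist.total_pairs,
                "adapter_fraction": insert_hist.adapter_fraction,
                "mode": insert_hist.mode(),
            }
            if insert_hist is not None
            else None
        ),
        duplication=(
            {
                "remaining_fraction": dup.remaining_fraction,
                "estimated_distinct": dup.estimated_distinct,
                "multiplicity": {str(k): v for k, v in dup.multiplicity.items()},
                "depth": dup.depth,
                "exact": dup.exact,
                "empty_reads": acc.sketch.empty_reads,
            }
            if dup
            else {"remaining_fraction": None, "estimated_distinct": 0,
                  "multiplicity": {}, "depth": 0, "exact": True, "empty_reads": 0}
        ),
        overrepresented={
            "sampled_reads": acc.fragments.sampled_reads,
            "distinct_fragments": len(acc.fragments.counts),
            "table_saturated": acc.fragments.table_saturated,
            "fragments": overrep_rows,
        },
        per_tile=tile_section,
        ont=ont_section,
        warnings=list(acc.ont.warnings),
    )
    _check_conservation(report)
    return report


def _round_vector(v) -> list:
    return [None if x != x else round(float(x), 4) for x in v]


def _round_matrix(m) -> list:
    return [_round_vector(row) for row in m]


def _check_conservation(report: QCReport) -> None:
    """Every per-read histogram must total the reads processed."""
    n = report.summary["total_reads"]
    pr = report.per_read
    checks = {
        "length_hist": sum(pr["length_hist"].values()),
        "gc_hist": sum(pr["gc_hist"]) + pr["gc_undefined"],
        "q_expected_error": sum(pr["q_hist_expected_error"]) + pr["empty_reads"],
        "q_arithmetic": sum(pr["q_hist_arithmetic"]) + pr["empty_reads"],
        "adapter_total": report.adapter_content["total_reads"],
    }
    for name, total in checks.items():
        if total != n:
            raise AssertionError(f"conservation violated in {name}: {total} != {n}")
    if report.insert_size is not None:
        hist = report.insert_size
        if sum(hist["histogram"].values()) + hist["undetermined"] != hist["total_pairs"]:
            raise AssertionError("insert-size histogram does not conserve pairs")


# --- serialisation ---------------------------------------------------------


def write_json(report: QCReport, path) -> None:
    data = report.to_dict()
    data["metadata"] = dict(data["metadata"])
    data["metadata"]["written_at"] = datetime.now(timezone.utc).isoformat()
    Path(path).write_text(json.dumps(data, sort_keys=True, indent=1))


def report_json_str(report: QCReport) -> str:
    """Deterministic JSON (no timestamp), used by the determinism tests."""
    return json.dumps(report.to_dict(), sort_keys=True)


def load_schema() -> dict:
    with resources.files("seqscope.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_against_schema(data: dict, schema: dict | None = None) -> None:
    """Structural validation against the bundled schema (a subset of
    JSON Schema: ``type``, ``required``, ``properties``)."""
    schema = schema or load_schema()
    _validate_node(data, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _validate_node(data, schema: dict, path: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = any(
            (data is None and t == "null") or
            (t != "null" and isinstance(data, _TYPES[t])
             and not (t in ("integer", "number") and isinstance(data, bool)))
            for t in allowed
        )
        if not ok:
            raise ValueError(f"{path}: expected {typ}, got {type(data).__name__}")
    if isinstance(data, dict):
        for key in schema.get("required", []):
            if key not in data:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in data:
                _validate_node(data[key], sub, f"{path}.{key}")


def write_html(report: QCReport, path) -> None:
    """Self-contained HTML report (no external references)."""
    import jinja2

    env = jinja2.Environment(
        loader=jinja2.PackageLoader("seqscope", "data"),
        autoescape=True,
    )
    template = env.get_template("report.html.j2")
    Path(path).write_text(template.render(r=report.to_dict()))
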