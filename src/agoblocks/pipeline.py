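"""End-to-end orchestration: simulate -> extract -> discover -> scan ->
consensus -> annotate, under one configuration, with a JSON run report.

The report is the machine-readable surface of a run: stage counts (proteins
in/kept/discarded, motifs accepted), per-clade consensus sequences and
specific blocks, the group consensus, named domain series, and — when the
run used synthetic data — recovery metrics against the planted truth.
Reports contain no timestamps, so identical config + seed reproduces a
byte-identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import consensus as cons
from . import domains as dom
from . import evaluate as ev
from . import io as agio
from . import motifs as fm
from . import simulate as sim
from .discovery import DiscoveryConfig, discover_blocks
from .scanning import Scanner

STAGES = ("simulate", "extract", "discover", "scan", "consensus", "annotate")


class ConfigError(Exception):
    """Invalid or inconsistent pipeline configuration (CLI exit code 2)."""


class StageError(Exception):
    """A pipeline stage failed (CLI exit code 1)."""


@dataclass
class PipelineConfig:
    """Stage toggles plus every stage parameter; see :func:`default_config`."""

    outdir: str = "agoblocks_run"
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage name -> bool
    # simulate
    scale: float = 1.0
    presence: float = sim.DEFAULT_PRESENCE
    conservation: float = sim.DEFAULT_CONSERVATION
    spacer_min: int = sim.DEFAULT_SPACER[0]
    spacer_max: int = sim.DEFAULT_SPACER[1]
    corruption_rate: float = 0.05
    # external inputs (used when simulate is off)
    proteins_fasta: Optional[str] = None
    cds_fasta: Optional[str] = None
    annotations_tsv: Optional[str] = None
    groups_tsv: Optional[str] = None
    # discover
    max_motifs: int = 50
    width_min: int = 8
    width_max: int = 50
    # scan / consensus / annotate
    models_path: Optional[str] = None  # default: packaged block table
    model_match_prob: float = sim.DEFAULT_CONSERVATION
    p_threshold: float = 1e-4
    gr_p_threshold: float = fm.GR_P_THRESHOLD
    consensus_threshold: float = 0.90
    group_k: int = 2
    n_terminal_fraction: float = 0.25
    # fixture paths (None = packaged)
    block_table_path: Optional[str] = None
    series_catalog_path: Optional[str] = None

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))


def default_config(outdir: str = "agoblocks_run", seed: int = 0) -> PipelineConfig:
    """The packaged default run: the four-clade synthetic family at full
    size (44 + 55 + 28 + 58 = 185 proteins), canonical-domain filtering,
    scanning with the packaged block models, consensus and annotation.
    Discovery is off by default (it is the expensive stage; enable it in the
    config or run the ``discover`` subcommand)."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        stages={
            "simulate": True,
            "extract": True,
            "discover": False,
            "scan": True,
            "consensus": True,
            "annotate": True,
        },
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    bad = set(cfg.stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    return cfg


def _validate(config: PipelineConfig) -> None:
    if not (0.0 < config.p_threshold < 1.0):
        raise ConfigError("p_threshold must be in (0, 1)")
    if not (0.0 < config.consensus_threshold <= 1.0):
        raise ConfigError("consensus_threshold must be in (0, 1]")
    if config.spacer_min < 0 or config.spacer_max < config.spacer_min:
        raise ConfigError("invalid spacer range")
    needs_inputs = not config.enabled("simulate") and any(
        config.enabled(s) for s in ("extract", "scan", "consensus", "discover", "annotate")
    )
    if needs_inputs and not config.proteins_fasta:
        raise ConfigError("proteins_fasta is required when simulate is disabled")
    for name in ("proteins_fasta", "cds_fasta", "annotations_tsv", "groups_tsv",
                 "models_path", "block_table_path", "series_catalog_path"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise ConfigError(f"{name}: no such file {path!r}")
    if config.enabled("extract") and not config.enabled("simulate"):
        if not (config.cds_fasta and config.annotations_tsv):
            raise ConfigError("extract needs cds_fasta and annotations_tsv")
    if config.enabled("consensus") and not config.enabled("simulate"):
        if not config.groups_tsv:
            raise ConfigError("consensus needs groups_tsv")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; returns (and writes) the report.

    Any stage failure raises before the report is written, so a failed run
    leaves no partial report.
    """
    _validate(config)
    outdir = Path(config.outdir)
    report: dict[str, Any] = {"stages_run": [s for s in STAGES if config.enabled(s)]}
    if not report["stages_run"]:
        return report

    outdir.mkdir(parents=True, exist_ok=True)
    proteins = cds_records = annotations = None
    groups: Optional[dict[str, str]] = None
    truth = None

    if config.enabled("simulate"):
        specs = sim.default_clade_specs(
            scale=config.scale,
            presence=config.presence,
            spacer_range=(config.spacer_min, config.spacer_max),
        )
        models = sim.table_models(conservation=config.conservation)
        proteins, truth = sim.generate_family(specs, models, seed=config.seed)
        cds_records, annotations = sim.generate_coding_and_annotations(
            proteins, truth, corruption_rate=config.corruption_rate, seed=config.seed
        )
        groups = {p.id: p.group for p in proteins}
        agio.write_fasta(proteins, outdir / "proteins.fasta")
        agio.write_fasta(cds_records, outdir / "cds.fasta")
        agio.write_annotations(annotations, outdir / "annotations.tsv")
        agio.write_group_assignments(groups, outdir / "groups.tsv")
        truth.to_json(outdir / "truth.json")
        report["simulate"] = {
            "n_proteins": len(proteins),
            "clade_sizes": {s.clade_id: s.n_members for s in specs},
        }
    else:
        if config.proteins_fasta:
            proteins = agio.read_fasta(config.proteins_fasta)
        if config.cds_fasta:
            cds_records = agio.read_cds_fasta(config.cds_fasta)
        if config.annotations_tsv:
            annotations = agio.read_annotations(config.annotations_tsv)
        if config.groups_tsv:
            groups = agio.read_group_assignments(config.groups_tsv)

    if config.enabled("extract"):
        results, kept, discarded = dom.extract_family(
            proteins, cds_records or [], annotations or []
        )
        agio.write_fasta(
            [sim.ProteinRecord(id=r.protein_id, sequence=r.extracted_aa)
             for r in results if r.kept and r.extracted_aa],
            outdir / "extracted.fasta",
        )
        with open(outdir / "discarded.tsv", "w") as fh:
            fh.write("protein_id\n")
            for pid in sorted(discarded):
                fh.write(pid + "\n")
        report["extract"] = {
            "n_in": len(proteins),
            "n_kept": len(kept),
            "n_discarded": len(discarded),
        }
        if truth is not None:
            report["extract"]["discard_matches_truth"] = (
                discarded == truth.should_be_discarded
            )
        # downstream stages see only the kept proteins
        proteins = [p for p in proteins if p.id in kept]

    if config.enabled("discover"):
        dconf = DiscoveryConfig(
            max_motifs=config.max_motifs,
            width_min=config.width_min,
            width_max=config.width_max,
            seed=config.seed,
        )
        motifs = discover_blocks(proteins, dconf)
        agio.serialize_block_models([m.model for m in motifs], outdir / "models.txt")
        report["discover"] = {
            "n_motifs": len(motifs),
            "widths": [m.width for m in motifs],
        }

    architectures = None
    scan_models = None
    if config.enabled("scan") or config.enabled("annotate"):
        if config.models_path:
            scan_models = agio.deserialize_block_models(config.models_path)
        else:
            scan_models = agio.load_block_table(
                config.block_table_path or agio.packaged_path("block_table.tsv"),
                match_prob=config.model_match_prob,
            )

    if config.enabled("scan"):
        scanner = Scanner(scan_models, p_threshold=config.p_threshold)
        architectures = [scanner.scan(p) for p in proteins]
        agio.write_architectures(architectures, outdir / "architectures.tsv")
        report["scan"] = {
            "n_proteins": len(architectures),
            "n_occurrences": sum(len(a.occurrences) for a in architectures),
        }
        if truth is not None:
            report["scan"]["architecture_match_rate"] = round(
                ev.architecture_match_rate(architectures, truth), 4
            )

    if config.enabled("consensus"):
        if architectures is None:
            raise StageError("consensus stage needs scan output")
        matrix = cons.build_presence_matrix(architectures, groups)
        consensuses = {}
        for clade in matrix.clades:
            consensuses[clade] = cons.clade_consensus(
                matrix, clade, architectures, threshold=config.consensus_threshold
            )
        specific = cons.clade_specific_blocks(matrix)
        for clade, cc in consensuses.items():
            cc.specific_blocks = specific[clade]
        group = cons.group_consensus(list(consensuses.values()), k=config.group_k)
        catalog = agio.load_series_catalog(config.series_catalog_path)
        series = {
            clade: [s.name for s in cons.name_domain_series(cc.ordered_blocks,
                                                            series_catalog=catalog)]
            for clade, cc in consensuses.items()
        }
        report["consensus"] = {
            "per_clade": {
                clade: {
                    "member_count": cc.member_count,
                    "ordered_blocks": cc.ordered_blocks,
                    "specific_blocks": sorted(cc.specific_blocks),
                    "series": series[clade],
                }
                for clade, cc in consensuses.items()
            },
            "group_consensus": sorted(group),
            "group_consensus_size": len(group),
        }
        if truth is not None:
            report["consensus"]["order_matches_truth"] = {
                clade: ev.consensus_order_matches(
                    cc.ordered_blocks, truth, clade, config.consensus_threshold
                )
                for clade, cc in consensuses.items()
            }
            report["consensus"]["specific_matches_truth"] = ev.specific_sets_match(
                specific, truth
            )
        payload = {
            clade: {
                "ordered_blocks": cc.ordered_blocks,
                "specific_blocks": sorted(cc.specific_blocks),
            }
            for clade, cc in consensuses.items()
        }
        payload["group_consensus"] = sorted(group)
        with open(outdir / "consensus.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    if config.enabled("annotate"):
        by_id = {m.block_id: m for m in scan_models}
        repeat_model = by_id.get(43)
        arch_by_id = {a.protein_id: a for a in (architectures or [])}
        rows = []
        gr_counts: dict[str, int] = {}
        for p in proteins:
            arch = arch_by_id.get(p.id)
            for hit in fm.find_xpg_sites(p, architecture=arch):
                rows.append((p.id, hit.motif_name, hit.position, hit.context))
            if repeat_model is not None:
                k = fm.count_gr_repeat_copies(
                    p,
                    repeat_model,
                    n_terminal_fraction=config.n_terminal_fraction,
                    p_threshold=config.gr_p_threshold,
                )
                gr_counts[p.id] = k
        with open(outdir / "motifs.tsv", "w") as fh:
            fh.write("protein_id\tmotif\tposition\tcontext\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        report["annotate"] = {
            "n_xpg_sites": len(rows),
            "n_proteins_with_repeats": sum(1 for k in gr_counts.values() if k > 0),
        }
        if truth is not None and gr_counts:
            report["annotate"]["repeat_count_accuracy"] = round(
                ev.repeat_count_accuracy(gr_counts, truth), 4
            )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


@dataclass
class FixtureReport:
    n_blocks: int
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_fixtures(
    block_table_path=None, series_catalog_path=None, clade_catalog_path=None
) -> FixtureReport:
    """Sanity-check the packaged (or user-supplied) fixture tables.

    Checks per-block width-vs-consensus agreement and domain tags (via the
    loader), and that every block cited by a series or clade row exists in
    the block table.  Returns all violations rather than stopping at the
    first.
    """
    violations: list[str] = []
    import pandas as pd

    t1 = block_table_path or agio.packaged_path("block_table.tsv")
    df = pd.read_csv(t1, sep="\t", comment="#", dtype=str)
    known_ids: set[int] = set()
    for _, row in df.iterrows():
        bid = int(row["block_id"])
        known_ids.add(bid)
        if int(row["length"]) != len(row["consensus"].strip()):
            violations.append(
                f"block {bid}: declared length {row['length']} != "
                f"consensus length {len(row['consensus'].strip())}"
            )
        tag = row["domain_tag"].strip()
        if tag not in ("PIWI", "PAZ", "DUF1785", "-", "–", "NONE"):
            violations.append(f"block {bid}: unknown domain tag {tag!r}")
    try:
        catalog = agio.load_series_catalog(series_catalog_path)
    except Exception as exc:  # unreadable file
        raise ValueError(f"cannot read series catalog: {exc}") from exc
    for s in catalog:
        for b in s.blocks:
            if b not in known_ids:
                violations.append(f"series {s.name}: unknown block {b}")
    clade_table = agio.load_clade_table(clade_catalog_path)
    series_names = {s.name for s in catalog}
    for _, row in clade_table.iterrows():
        for name in row["series"]:
            if name not in series_names:
                violations.append(f"clade {row['clade']}: unknown series {name!r}")
        for b in row["specific_blocks"]:
            if b not in known_ids:
                violations.append(f"clade {row['clade']}: unknown specific block {b}")
    return FixtureReport(n_blocks=len(df), violations=violations)
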