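"""End-to-end pipeline runs and human-readable reports.

A single YAML config drives segregation filtering, IBD intersection,
linkage on the surviving sites, and gene ranking; every number in the
resulting :class:`RunReport` comes from a module output, and regenerating
the report from the same inputs and seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .ibdshare import SharedRegion, read_gene_spans, read_ibd, shared_regions
from .linkstats import DiseaseModel, LinkageResult, single_point_lod
from .pedio import read_ped
from .segfilter import CascadeConfig, FilterLedger, SegregationPattern, rank_survivors, run_cascade
from .simfam import simulate_family, study_emulation_preset
from .varstore import read_annotated_vcf


@dataclass
class RunReport:
    config: dict
    ledger: FilterLedger
    linkage: list[tuple[str, LinkageResult]]
    ranked_genes: list[str]
    version: str
    seed: int

    def to_text(self) -> str:
        lines = [
            f"fampri {self.version} run report (seed={self.seed})",
            "",
            "Filter cascade",
            self.ledger.to_frame().to_string(index=False),
            "",
            "Single-point parametric linkage",
        ]
        if self.linkage:
            rows = [{"site": site, "lod": f"{r.lod:.3f}", "p_value": f"{r.p_value:.3g}"}
                    for site, r in self.linkage]
            lines.append(pd.DataFrame(rows).to_string(index=False))
        else:
            lines.append("(no surviving sites)")
        lines += ["", "Ranked candidate genes",
                  "\n".join(f"{i + 1}. {g}" for i, g in enumerate(self.ranked_genes))
                  or "(none)"]
        return "\n".join(lines) + "\n"


def _require(cfg: dict, key: str, context: str = "config") -> object:
    if key not in cfg or cfg[key] in (None, [], {}):
        raise ConfigurationError(f"{context}: missing required key {key!r}")
    return cfg[key]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check; raises ConfigurationError before any computation."""
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config needs either a 'simulate' or an 'inputs' section")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("vcf", "ped"):
            _require(inputs, key, "inputs")
    pattern = _require(cfg, "pattern")
    _require(pattern, "affected", "pattern")
    _require(pattern, "unaffected", "pattern")


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunReport:
    """Execute segregation -> cascade -> IBD -> linkage -> ranking.

    ``config`` is a mapping or a YAML path; see the repository README for
    the schema.  When ``out_dir`` is given, writes ledger.tsv, linkage.tsv,
    ranked_genes.txt and report.txt there.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))

    if "simulate" in cfg:
        sim_section = cfg["simulate"] or {}
        sim_dir = sim_section.get("out_dir")
        sim = simulate_family(study_emulation_preset(seed=seed),
                              out_dir=sim_dir)
        pedigree = sim.pedigree
        variants = sim.variants
        segments = [seg for pair, tr in sim.truth.ibd_tracts.items()
                    for seg in _tracts_to_segments(pair, tr)]
        gene_spans = sim.gene_spans
    else:
        inputs = cfg["inputs"]
        pedigree = read_ped(inputs["ped"])
        variants = read_annotated_vcf(inputs["vcf"], inputs.get("annotations"))
        segments = read_ibd(inputs["ibd"]) if inputs.get("ibd") else []
        gene_spans = read_gene_spans(inputs["gene_spans"]) if inputs.get("gene_spans") else {}

    pattern = SegregationPattern(
        affected_ids=tuple(cfg["pattern"]["affected"]),
        unaffected_ids=tuple(cfg["pattern"]["unaffected"]))
    cascade_cfg = CascadeConfig(**(cfg.get("cascade") or {}))
    regions: list[SharedRegion] = []
    if segments and len(pattern.affected_ids) >= 2:
        regions = shared_regions(segments, set(pattern.affected_ids))
    ledger = run_cascade(variants, pattern, cascade_cfg, regions, gene_spans=gene_spans)

    link_cfg = cfg.get("linkage") or {}
    model = DiseaseModel(
        prevalence=float(link_cfg.get("prevalence", 0.01)),
        penetrances=tuple(link_cfg.get("penetrance", (0.0, 0.9, 0.9))))
    marker_af = float(link_cfg.get("marker_af", 0.001))
    linkage: list[tuple[str, LinkageResult]] = []
    for v in ledger.final_survivors():
        marker_genotypes = {iid: g for iid, g in v.genotypes.items() if iid in pedigree}
        res = single_point_lod(pedigree, marker_genotypes, model, marker_af=marker_af)
        linkage.append((f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}", res))

    ranked = rank_survivors(ledger, seed_genes=(cfg.get("ranking") or {}).get("seed_genes"))
    report = RunReport(config=cfg, ledger=ledger, linkage=linkage,
                       ranked_genes=ranked, version=__version__, seed=seed)
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _tracts_to_segments(pair: tuple[str, str], tracts: list[tuple[str, int, int]]):
    from .ibdshare import IBDSegment
    return [IBDSegment(pair[0], pair[1], chrom, a, b) for chrom, a, b in tracts]


def _write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.ledger.write_tsv(out / "ledger.tsv")
    rows = [{"site": site, "lod": r.lod, "p_value": r.p_value,
             "loglik_linked": r.loglik_linked, "loglik_unlinked": r.loglik_unlinked}
            for site, r in report.linkage]
    pd.DataFrame(rows, columns=["site", "lod", "p_value", "loglik_linked",
                                "loglik_unlinked"]).to_csv(out / "linkage.tsv", sep="\t", index=False)
    (out / "ranked_genes.txt").write_text(
        "".join(f"{g}\n" for g in report.ranked_genes))
    (out / "report.txt").write_text(report.to_text())
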