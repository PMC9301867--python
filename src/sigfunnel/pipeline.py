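"""End-to-end orchestration and report rendering.

``run_all`` wires the stages together: read inputs, classify
consequences, run the prioritization funnel, compute six-class spectra,
build the SBS96 matrix and refit signature exposures, and select
case-specific recurrent CNV start sites.  The output bundle is
deterministic for fixed inputs and configuration:

* ``funnel_report.json`` — per-stage gene/mutation counts;
* ``final_genes.txt`` / ``final_records.tsv`` — the surviving genes and
  their mutations;
* ``spectrum.tsv`` — six-class frequencies per group;
* ``sbs96.tsv`` / ``exposures.tsv`` — channel counts and signature
  percentages (when a catalog is configured);
* ``cnv_specific.bed`` — case-specific recurrent CNV events (when CNV
  tables are configured);
* ``run_config.yaml`` — the effective configuration, echoed back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import io as io_mod
from .consequence import annotate_consequences
from .funnel import FunnelConfig, FunnelReport, RecurrenceUnit, run_funnel
from .records import Group
from .signatures import build_sbs96_matrix, read_signature_catalog, refit_matrix
from .spectrum import SIX_CLASSES, SummaryMode, group_spectrum_summary

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "case", "control", "sample_sheet", "drivers", "reported", "catalog",
    "cnv_case", "cnv_control", "out", "af_max_known", "recurrence_min",
    "recurrence_unit", "require_amino_acid_change", "spectrum_mode",
    "prune_below", "cnv_min_samples", "reclassify", "seed",
}


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    case: str
    control: str
    sample_sheet: str
    drivers: str
    reported: tuple = ()
    catalog: Optional[str] = None
    cnv_case: Optional[str] = None
    cnv_control: Optional[str] = None
    out: str = "report"
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    spectrum_mode: SummaryMode = SummaryMode.MEAN_OF_SAMPLES
    prune_below: float = 0.0
    cnv_min_samples: int = 2
    reclassify: bool = False
    seed: int = 0

    @staticmethod
    def from_mapping(data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        funnel = FunnelConfig(
            af_max_known=float(data.get("af_max_known", 0.0)),
            recurrence_min=int(data.get("recurrence_min", 2)),
            recurrence_unit=RecurrenceUnit(data.get("recurrence_unit", "SAMPLE")),
            require_amino_acid_change=bool(data.get("require_amino_acid_change", True)),
        )
        return RunConfig(
            case=data["case"],
            control=data["control"],
            sample_sheet=data["sample_sheet"],
            drivers=data["drivers"],
            reported=tuple(data.get("reported", ())),
            catalog=data.get("catalog"),
            cnv_case=data.get("cnv_case"),
            cnv_control=data.get("cnv_control"),
            out=str(data.get("out", "report")),
            funnel=funnel,
            spectrum_mode=SummaryMode(data.get("spectrum_mode", "MEAN_OF_SAMPLES")),
            prune_below=float(data.get("prune_below", 0.0)),
            cnv_min_samples=int(data.get("cnv_min_samples", 2)),
            reclassify=bool(data.get("reclassify", False)),
            seed=int(data.get("seed", 0)),
        )

    def echo(self) -> dict:
        return {
            "case": self.case,
            "control": self.control,
            "sample_sheet": self.sample_sheet,
            "drivers": self.drivers,
            "reported": list(self.reported),
            "catalog": self.catalog,
            "cnv_case": self.cnv_case,
            "cnv_control": self.cnv_control,
            "out": self.out,
            "af_max_known": self.funnel.af_max_known,
            "recurrence_min": self.funnel.recurrence_min,
            "recurrence_unit": self.funnel.recurrence_unit.value,
            "require_amino_acid_change": self.funnel.require_amino_acid_change,
            "spectrum_mode": self.spectrum_mode.value,
            "prune_below": self.prune_below,
            "cnv_min_samples": self.cnv_min_samples,
            "reclassify": self.reclassify,
            "seed": self.seed,
        }


def render_funnel_report(report: FunnelReport) -> str:
    """Human-readable per-stage lines: "stage  group  genes (mutations)"."""
    lines = []
    for s in report.stages:
        lines.append(f"{s.stage:<12}{s.group:<9}{s.gene_count:>6} ({s.mutation_count})")
    lines.append("final genes: " + (", ".join(report.final_genes) or "(none)"))
    return "\n".join(lines) + "\n"


def run_all(cfg: RunConfig) -> FunnelReport:
    """Execute every stage and write the output bundle under ``cfg.out``."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    samples = io_mod.read_sample_sheet(cfg.sample_sheet)
    case = io_mod.read_variant_table(cfg.case, samples)
    control = io_mod.read_variant_table(cfg.control, samples)
    annotate_consequences(case, reclassify=cfg.reclassify)
    annotate_consequences(control, reclassify=cfg.reclassify)
    log.info("loaded %d case and %d control records", len(case), len(control))

    drivers = io_mod.read_gene_list(cfg.drivers, "driver_catalog")
    reported = [
        io_mod.read_gene_list(p, f"reported_{i}") for i, p in enumerate(cfg.reported)
    ]

    report = run_funnel(case, control, drivers, reported, cfg.funnel)
    (out / "funnel_report.json").write_text(report.to_json() + "\n")
    (out / "funnel_report.txt").write_text(render_funnel_report(report))
    io_mod.write_gene_list(report.final_genes, out / "final_genes.txt")
    io_mod.write_table(report.final_records, out / "final_records.tsv")

    spec_rows = {}
    for group, records in ((Group.CASE, case), (Group.CONTROL, control)):
        if records:
            spec = group_spectrum_summary(records, group, cfg.spectrum_mode)
            spec_rows[group.value] = [spec.freqs[c] for c in SIX_CLASSES]
    pd.DataFrame(spec_rows, index=list(SIX_CLASSES)).to_csv(out / "spectrum.tsv", sep="\t")

    matrix = build_sbs96_matrix(case + control)
    matrix.to_csv(out / "sbs96.tsv", sep="\t")
    if cfg.catalog:
        catalog = read_signature_catalog(cfg.catalog)
        exposures = refit_matrix(matrix[matrix.sum(axis=1) > 0], catalog, cfg.prune_below)
        exposures.to_csv(out / "exposures.tsv", sep="\t")

    if cfg.cnv_case and cfg.cnv_control:
        case_events = cnv_mod.read_cnv_table(cfg.cnv_case)
        control_events = cnv_mod.read_cnv_table(cfg.cnv_control)
        survivors, n_keys, n_events = cnv_mod.group_specific_events(
            case_events, control_events, cfg.cnv_min_samples
        )
        cnv_mod.write_cnv_table(survivors, out / "cnv_specific.bed")
        log.info("CNV: %d case-specific keys covering %d events", n_keys, n_events)

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.echo(), fh, sort_keys=True)
    return report
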