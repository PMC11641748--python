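"""Run configuration and the end-to-end control/treated pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .align import Scoring, align_readset
from .classify import ClassifierParams, classify_locus, corrected_efficiency
from .quant import (
    AlleleTable,
    Amplicon,
    GuideSpec,
    allele_table,
    quantify,
    render_allele_table,
)
from .windows import DualWindowResult, ThresholdSpec


@dataclass
class SampleAnalysis:
    """All per-sample quantities computed from one alignment pass."""

    aee: dict[int, float]  # window width -> AEE
    n_discarded: int
    dual: DualWindowResult
    alleles: AlleleTable


def analyze_sample(
    reads,
    amplicon: Amplicon,
    guide: GuideSpec,
    widths: tuple[int, ...] = (2, 20),
    report_span: int = 40,
    scoring: Scoring | None = None,
) -> SampleAnalysis:
    """Align once; compute AEE per window, the dual-window contrast and alleles."""
    from .quant import _as_sequences

    aligned = align_readset(_as_sequences(reads), amplicon.sequence, scoring)
    results = {w: quantify((), amplicon, guide, w, aligned=aligned) for w in widths}
    dual = DualWindowResult(aee2=results[2].aee, aee20=results[20].aee)
    alleles = allele_table((), amplicon, guide, report_span=report_span, aligned=aligned)
    return SampleAnalysis(
        aee={w: r.aee for w, r in results.items()},
        n_discarded=results[widths[0]].n_discarded,
        dual=dual,
        alleles=alleles,
    )


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Declarative configuration for one amplicon run.

    Defaults follow the published analysis settings where stated: window
    widths 2 and 20 nt, and a 10-pp discrepancy threshold when none is
    derived from a positive control.
    """

    amplicon: Amplicon
    guide: GuideSpec
    widths: tuple[int, ...] = (2, 20)
    threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec(10.0, "fixed"))
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    scoring: Scoring = field(default_factory=Scoring)
    report_span: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.widths) < 1 or any(w % 2 or w <= 0 for w in self.widths):
            raise ConfigError("window widths must be positive even integers")
        if list(self.widths) != sorted(self.widths):
            raise ConfigError("window widths must be ascending")
        try:
            self.guide.validate_against(self.amplicon)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            amplicon = Amplicon(**raw["amplicon"])
            guide = GuideSpec(**raw["guide"])
            kwargs = {}
            if "widths" in raw:
                kwargs["widths"] = tuple(raw["widths"])
            if "threshold" in raw:
                kwargs["threshold"] = ThresholdSpec(**raw["threshold"])
            if "classifier" in raw:
                kwargs["classifier"] = ClassifierParams(**raw["classifier"])
            if "scoring" in raw:
                kwargs["scoring"] = Scoring(**raw["scoring"])
            for key in ("report_span", "seed"):
                if key in raw:
                    kwargs[key] = raw[key]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        return cls(amplicon=amplicon, guide=guide, **kwargs)

    def echo(self) -> dict:
        """Full parameter echo for provenance logging."""
        return {
            "amplicon": {"id": self.amplicon.id, "length": len(self.amplicon)},
            "guide": {
                "protospacer": self.guide.protospacer,
                "pam": self.guide.pam,
                "strand": self.guide.strand,
                "protospacer_start": self.guide.protospacer_start,
                "cut_offset": self.guide.cut_offset,
            },
            "widths": list(self.widths),
            "threshold_pp": self.threshold.value_pp,
            "threshold_provenance": self.threshold.provenance,
            "classifier": vars(self.classifier).copy(),
            "scoring": vars(self.scoring).copy(),
            "report_span": self.report_span,
            "seed": self.seed,
        }


def _allele_tsv(table: AlleleTable, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "aligned_sequence": r.aligned_sequence,
                "count": r.count,
                "frequency": r.frequency,
                "events": ";".join(
                    f"{e.kind[0]}:{e.ref_start}:{e.ref_length}:{e.alt}" for e in r.events
                ),
                "modified_in_window": r.modified_in_window,
            }
            for r in table.records
        ]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: RunConfig,
    control_reads,
    treated_reads=None,
    outdir: str | Path | None = None,
) -> dict:
    """Quantify, contrast windows, classify variation, correct efficiency.

    ``treated_reads`` may be omitted for a control-only run (classification
    then proceeds without the treated-match evidence).  When ``outdir`` is
    given, writes summary.json, per-sample allele TSVs and a plain-text
    allele rendering.
    """
    ctrl = analyze_sample(
        control_reads, config.amplicon, config.guide,
        widths=config.widths, report_span=config.report_span, scoring=config.scoring,
    )
    summary: dict = {"config": config.echo(), "control": {
        "aee": {str(w): v for w, v in ctrl.aee.items()},
        "delta_pp": ctrl.dual.delta_pp,
        "n_discarded": ctrl.n_discarded,
    }}
    trt = None
    if treated_reads is not None:
        trt = analyze_sample(
            treated_reads, config.amplicon, config.guide,
            widths=config.widths, report_span=config.report_span, scoring=config.scoring,
        )
        summary["treated"] = {
            "aee": {str(w): v for w, v in trt.aee.items()},
            "delta_pp": trt.dual.delta_pp,
            "n_discarded": trt.n_discarded,
        }
    call = classify_locus(
        ctrl.dual, ctrl.alleles, trt.alleles if trt else None,
        config.threshold, config.classifier,
    )
    summary["classification"] = {"label": call.label, "evidence": call.evidence}
    if trt is not None:
        summary["corrected_efficiency_w20"] = corrected_efficiency(
            trt.alleles, ctrl.alleles, width=20, params=config.classifier
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        _allele_tsv(ctrl.alleles, outdir / "control_alleles.tsv")
        rendering = ["== control ==", render_allele_table(ctrl.alleles, config.amplicon)]
        if trt is not None:
            _allele_tsv(trt.alleles, outdir / "treated_alleles.tsv")
            rendering += ["", "== treated ==", render_allele_table(trt.alleles, config.amplicon)]
        (outdir / "alleles.txt").write_text("\n".join(rendering) + "\n")
    summary["_control"] = ctrl
    if trt is not None:
        summary["_treated"] = trt
    return summary
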