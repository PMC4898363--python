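"""End-to-end orchestration of the compositional-signature analysis.

One call runs the whole flow for a genome: region annotation -> per-region
composition -> dinucleotide suppression ratios -> cumulative skew tracks ->
ss/ds partition of the folded genome (when ss-count data is supplied) ->
compartment composition and skew -> codon usage (GC3, ENCobs, ENCexp,
ratio), and writes table-style TSVs plus a full-precision JSON report.

Configuration is a plain dict (or a YAML file with the same keys):

    fasta: genome FASTA path (first record analyzed unless `record_id` set)
    sscount: one path, or a list of two fragment paths merged with `overlap`
    annotation: optional region TSV (else the polyprotein ORF is detected)
    outdir: optional output directory
    window_frac / step_frac / overlap / tie_delta: analysis parameters
"""

from __future__ import annotations

import hashlib
import logging
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .codon_usage import (
    CodonUsageTable,
    codon_counts,
    codon_usage_report,
    enc_expected,
    enc_observed,
    enc_ratio,
    gc3,
)
from .composition import (
    CompositionProfile,
    DinucleotideCounts,
    composition_table,
    count_dinucleotides,
    count_nucleotides,
    count_nucleotides_multiset,
    dinucleotide_ratio,
)
from .sequence_io import (
    GenomeRecord,
    RegionAnnotation,
    find_polyprotein_orf,
    read_fasta,
    read_region_annotation,
    slice_regions,
    write_fasta,
)
from .skew import SkewTrack, all_pairwise_skews
from .structure import (
    PairingProfile,
    classify_ss_ds,
    merge_fragment_profiles,
    partition_positions,
    read_sscount,
)

DEFAULT_PARAMS = {
    "window_frac": 0.01,
    "step_frac": 0.2,
    "overlap": 1000,
    "tie_delta": 0.02,
    "ss_threshold": 0.5,  # fraction of structures; the at-least-half rule
}


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisReport:
    """All stage outputs for one genome, recomputable from inputs + provenance."""

    record: GenomeRecord
    annotation: RegionAnnotation
    region_profiles: dict[str, CompositionProfile]
    dinucleotides: DinucleotideCounts
    dinucleotide_ratios: dict[str, float | None]
    skew_tracks: dict[str, dict[str, SkewTrack]]  # compartment -> pair -> track
    codon_table: CodonUsageTable
    codon_stats: dict[str, float]
    partition: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "record": {"id": self.record.id, "length": self.record.length},
            "annotation": {
                "utr5": list(self.annotation.utr5),
                "orf": list(self.annotation.orf),
                "utr3": list(self.annotation.utr3),
            },
            "regions": {
                name: {
                    "counts": dict(p.counts),
                    "total": p.total,
                    "pu_py_ratio": p.pu_py_ratio,
                    "purine_fraction": p.purine_fraction if p.total else None,
                }
                for name, p in self.region_profiles.items()
            },
            "dinucleotides": dict(self.dinucleotides.counts),
            "dinucleotide_ratios": self.dinucleotide_ratios,
            "codon_usage": {
                "counts": dict(self.codon_table.counts),
                "n_codons": self.codon_table.n_codons,
                **self.codon_stats,
            },
            "skew_final_cumulative": {
                comp: {pair: float(t.cumulative[-1]) for pair, t in tracks.items()}
                for comp, tracks in self.skew_tracks.items()
            },
            "provenance": self.provenance,
        }
        if self.partition:
            d["partition"] = {
                k: v for k, v in self.partition.items() if k not in ("ss_seq", "ds_seq")
            }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "fasta" not in config:
        raise PipelineError("config must provide at least a 'fasta' path")
    return dict(config)


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"stage {name!r} failed: {exc}")

    return wrap


def run_analysis(config: Mapping[str, Any] | str | Path) -> AnalysisReport:
    """Run the full analysis described by ``config``; see module docstring.

    Missing ss-count data downgrades the structure stages to a warning (the
    report simply lacks the ds/ss sections); any other stage error raises
    :class:`PipelineError` naming the stage.
    """
    cfg = _load_config(config)
    params = {**DEFAULT_PARAMS, **{k: cfg[k] for k in DEFAULT_PARAMS if k in cfg}}

    fasta = Path(cfg["fasta"])
    try:
        records = read_fasta(fasta, skip_ambiguous=bool(cfg.get("skip_ambiguous", False)))
    except Exception as exc:
        raise _stage("sequence_io")(exc) from exc
    if cfg.get("record_id"):
        matches = [r for r in records if r.id == cfg["record_id"]]
        if not matches:
            raise PipelineError(f"record {cfg['record_id']!r} not in {fasta}")
        record = matches[0]
    else:
        record = records[0]

    try:
        if cfg.get("annotation"):
            annotation = read_region_annotation(cfg["annotation"])
            annotation.validate_against(record)
        else:
            annotation = find_polyprotein_orf(record)
        utr5, orf, utr3 = slice_regions(record, annotation)
    except Exception as exc:
        raise _stage("regions")(exc) from exc

    try:
        region_profiles = {
            "complete": count_nucleotides(record.sequence),
            "utr5": count_nucleotides(utr5),
            "utr3": count_nucleotides(utr3),
            "utr5+utr3": count_nucleotides_multiset(utr5 + utr3),
            "orf": count_nucleotides(orf),
        }
        dinucs = count_dinucleotides(record.sequence)
        dinuc_ratios = {
            "GpC/CpG": dinucleotide_ratio(dinucs, "GC", "CG"),
            "ApU/UpA": dinucleotide_ratio(dinucs, "AU", "UA"),
            "GpA/ApG": dinucleotide_ratio(dinucs, "GA", "AG"),
            "CpU/UpC": dinucleotide_ratio(dinucs, "CU", "UC"),
        }
    except Exception as exc:
        raise _stage("composition")(exc) from exc

    try:
        skew_tracks = {
            "all": all_pairwise_skews(
                record.sequence, params["window_frac"], params["step_frac"]
            )
        }
    except Exception as exc:
        raise _stage("skew")(exc) from exc

    partition: dict[str, Any] = {}
    sscount = cfg.get("sscount")
    if not sscount:
        logging.getLogger(__name__).warning(
            "no ss-count data supplied; skipping ss/ds partition and "
            "compartment composition/skew"
        )
    if sscount:
        try:
            paths = [sscount] if isinstance(sscount, (str, Path)) else list(sscount)
            profiles = [
                read_sscount(p, n_structures=cfg.get("n_structures")) for p in paths
            ]
            profile = profiles[0]
            for nxt in profiles[1:]:
                profile = merge_fragment_profiles(profile, nxt, params["overlap"])
            if profile.length != record.length:
                raise PipelineError(
                    f"merged ss-count length {profile.length} != genome {record.length}"
                )
            mask = classify_ss_ds(profile)
            ss_seq, ds_seq = partition_positions(record, mask)
            partition = {
                "n_structures": profile.n_structures,
                "ss_length": len(ss_seq),
                "ds_length": len(ds_seq),
                "ss_fraction": len(ss_seq) / record.length,
                "ss_seq": ss_seq,
                "ds_seq": ds_seq,
            }
            region_profiles["ss"] = count_nucleotides_multiset(ss_seq)
            region_profiles["ds"] = count_nucleotides_multiset(ds_seq)
            # compartment skew uses the same fractional window scheme on the
            # ordered concatenated subsequences
            skew_tracks["ds"] = all_pairwise_skews(
                ds_seq, params["window_frac"], params["step_frac"]
            )
            skew_tracks["ss"] = all_pairwise_skews(
                ss_seq, params["window_frac"], params["step_frac"]
            )
        except Exception as exc:
            raise _stage("structure_partition")(exc) from exc

    try:
        table = codon_counts(orf)
        s = gc3(table)
        obs = enc_observed(table)
        exp = enc_expected(s)
        codon_stats = {
            "gc3": s,
            "enc_obs": obs,
            "enc_exp": exp,
            "enc_ratio": enc_ratio(obs, exp),
        }
    except Exception as exc:
        raise _stage("codon_usage")(exc) from exc

    provenance = {
        "version": __version__,
        "parameters": params,
        "inputs": {"fasta": {"path": str(fasta), "sha256": _sha256(fasta)}},
    }
    if sscount:
        provenance["inputs"]["sscount"] = [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in paths
        ]

    report = AnalysisReport(
        record=record,
        annotation=annotation,
        region_profiles=region_profiles,
        dinucleotides=dinucs,
        dinucleotide_ratios=dinuc_ratios,
        skew_tracks=skew_tracks,
        codon_table=table,
        codon_stats=codon_stats,
        partition=partition,
        provenance=provenance,
    )
    if cfg.get("outdir"):
        write_report(report, cfg["outdir"], figures=bool(cfg.get("figures", False)))
    return report


def write_report(report: AnalysisReport, outdir: str | Path, figures: bool = False) -> None:
    """Write TSV tables, compartment FASTAs and the JSON report to ``outdir``.

    Re-running with identical inputs and parameters produces byte-identical
    TSV/JSON output (figures exempt).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    order = [r for r in ("complete", "utr5", "utr3", "utr5+utr3", "orf", "ds", "ss")
             if r in report.region_profiles]
    composition_table({r: report.region_profiles[r] for r in order}).to_csv(
        out / "composition.tsv", sep="\t"
    )

    di = pd.DataFrame(
        sorted(report.dinucleotides.counts.items()), columns=["dinucleotide", "count"]
    )
    di.to_csv(out / "dinucleotides.tsv", sep="\t", index=False)

    for comp, tracks in report.skew_tracks.items():
        for pair, track in tracks.items():
            track.to_frame().to_csv(
                out / f"skew_{comp}_{pair}.tsv", sep="\t", index=False,
                float_format="%.6f",
            )

    codon_usage_report(report.codon_table).to_csv(
        out / "codon_usage.tsv", sep="\t", index=False
    )

    if report.partition:
        write_fasta(
            [
                GenomeRecord(id=f"{report.record.id}|ss",
                             sequence=report.partition["ss_seq"]),
                GenomeRecord(id=f"{report.record.id}|ds",
                             sequence=report.partition["ds_seq"]),
            ],
            out / "partition.fasta",
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    if figures:
        from .skew import skew_panel

        skew_panel(report.skew_tracks, str(out / "skew_panels.png"))


def compare_isolates(
    reports: Sequence[AnalysisReport] | None = None,
    configs: Sequence[Mapping[str, Any] | str | Path] | None = None,
) -> pd.DataFrame:
    """Long-format cross-isolate summary (composition, Pu/Py, GC3/ENC points).

    Accepts already-computed reports or configs to run; one row per isolate
    per metric, ready for an Nc-plot or a composition comparison.
    """
    if reports is None:
        if not configs or len(configs) < 1:
            raise PipelineError("provide reports or configs")
        reports = [run_analysis(c) for c in configs]
    rows = []
    for rep in reports:
        prof = rep.region_profiles["complete"]
        fr = prof.fractions
        metrics = {
            **{f"frac_{n}": fr[n] for n in "AUCG"},
            "pu_py_ratio": prof.pu_py_ratio,
            "purine_fraction": prof.purine_fraction,
            "gc3": rep.codon_stats["gc3"],
            "enc_obs": rep.codon_stats["enc_obs"],
            "enc_exp": rep.codon_stats["enc_exp"],
            "enc_ratio": rep.codon_stats["enc_ratio"],
        }
        for metric, value in metrics.items():
            rows.append({"isolate": rep.record.id, "metric": metric, "value": value})
    return pd.DataFrame(rows)
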