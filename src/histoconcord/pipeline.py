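"""End-to-end orchestration: evaluate structure sets, assemble cohort
tables, run the statistical comparisons, and read/write everything.

This is the library layer behind the command-line interface: given
per-patient structure sets (real, from NIfTI manifests, or synthetic, from
:mod:`histoconcord.synthetic_phantom`), it trims the GTVs to the gland,
scores every requested partition scheme, runs the lesion and voxel-level
analyses, and produces tidy :class:`pandas.DataFrame` tables that the
cohort statistics consume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import ComparisonReport, compare_many, compare_two
from .errors import UndefinedMetricError
from .lesion_analysis import (
    DEFAULT_CONNECTIVITY,
    INDEX_DIAMETER_MM,
    analyse_lesions,
)
from .mask_model import StructureSet, VoxelMask, assert_shared_grid, trim_gtv, volume_ml, write_mask
from .overlap_metrics import overlap
from .partitioning import Scheme, partition
from .segment_scoring import PositivityRule, score_scheme
from .synthetic_phantom import PhantomTruth

ALL_SCHEMES = (Scheme.QUADRANT_SLICE, Scheme.SEG18, Scheme.SEG6)


@dataclass(frozen=True)
class RunConfig:
    schemes: tuple[Scheme, ...] = ALL_SCHEMES
    rule: PositivityRule = PositivityRule()
    connectivity: int = DEFAULT_CONNECTIVITY
    index_diameter_mm: float = INDEX_DIAMETER_MM
    thirds_mode: str = "slices"
    quadrant_split: str = "centroid"
    alpha: float = 0.05
    master_seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = [s.value for s in self.schemes]
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PatientResult:
    patient_id: str
    segment_rows: list[dict]
    dsc_rows: list[dict]
    lesion_rows: list[dict]
    volume_rows: list[dict]


def _partition_kwargs(config: RunConfig, scheme: Scheme) -> dict:
    if scheme is Scheme.QUADRANT_SLICE:
        return {"split": config.quadrant_split}
    return {"thirds_mode": config.thirds_mode}


def evaluate_structure_set(
    sset: StructureSet, config: RunConfig = RunConfig()
) -> PatientResult:
    """Run all requested analyses for one patient.

    GTVs are trimmed to the gland (and to the examined region when one is
    provided) before any scoring.
    """
    assert_shared_grid(sset)
    reference = trim_gtv(sset.reference, sset.gland, sset.examined_region)
    tests = {
        name: trim_gtv(mask, sset.gland, sset.examined_region)
        for name, mask in sset.tests.items()
    }
    labelmaps = {
        scheme: partition(sset.gland, scheme, **_partition_kwargs(config, scheme))
        for scheme in config.schemes
    }

    segment_rows = []
    for scheme, labelmap in labelmaps.items():
        for name, mask in tests.items():
            perf = score_scheme(labelmap, reference, mask, config.rule)
            row = {"patient_id": sset.patient_id, "modality": name}
            row.update(perf.as_row())
            segment_rows.append(row)

    dsc_rows = []
    for name, mask in tests.items():
        try:
            res = overlap(reference, mask)
            dsc_val: float = res.dsc
            inter = res.intersection_ml
        except UndefinedMetricError:
            dsc_val, inter = math.nan, math.nan
        dsc_rows.append(
            {
                "patient_id": sset.patient_id,
                "modality": name,
                "dsc": dsc_val,
                "intersection_ml": inter,
                "reference_ml": volume_ml(reference),
                "test_ml": volume_ml(mask),
            }
        )

    lesion_rows = []
    for name, mask in tests.items():
        table = analyse_lesions(
            reference,
            mask,
            rule=config.rule,
            connectivity=config.connectivity,
            min_diameter_mm=config.index_diameter_mm,
        )
        lesion_rows.append(
            {
                "patient_id": sset.patient_id,
                "modality": name,
                "n_index_lesions": len(table.matches),
                "n_detected": table.n_detected,
                "n_false_positive": len(table.false_positive_lesions),
                "false_positive_diameters_mm": ";".join(
                    f"{l.max_diameter_mm:.1f}" for l in table.false_positive_lesions
                ),
            }
        )

    volume_rows = [
        {
            "patient_id": sset.patient_id,
            "structure": "reference",
            "volume_ml": volume_ml(reference),
        }
    ] + [
        {"patient_id": sset.patient_id, "structure": name, "volume_ml": volume_ml(mask)}
        for name, mask in tests.items()
    ]
    return PatientResult(sset.patient_id, segment_rows, dsc_rows, lesion_rows, volume_rows)


@dataclass
class CohortResult:
    segments: pd.DataFrame
    dsc: pd.DataFrame
    lesions: pd.DataFrame
    volumes: pd.DataFrame
    config: RunConfig

    def sensitivity_table(self, scheme: Scheme | str) -> pd.DataFrame:
        """Patients x modalities sensitivity matrix for one scheme."""
        return self._metric_table("sensitivity", scheme)

    def specificity_table(self, scheme: Scheme | str) -> pd.DataFrame:
        return self._metric_table("specificity", scheme)

    def _metric_table(self, metric: str, scheme: Scheme | str) -> pd.DataFrame:
        scheme = Scheme(scheme)
        sub = self.segments[self.segments["scheme"] == scheme.value]
        return sub.pivot(index="patient_id", columns="modality", values=metric)

    def scheme_table(self, metric: str, modality: str) -> pd.DataFrame:
        """Patients x schemes matrix of one metric for one modality."""
        sub = self.segments[self.segments["modality"] == modality]
        return sub.pivot(index="patient_id", columns="scheme", values=metric)

    def dsc_table(self) -> pd.DataFrame:
        return self.dsc.pivot(index="patient_id", columns="modality", values="dsc")


def evaluate_cohort(
    ssets: list[StructureSet], config: RunConfig = RunConfig()
) -> CohortResult:
    results = [evaluate_structure_set(s, config) for s in ssets]
    return CohortResult(
        segments=pd.DataFrame([r for p in results for r in p.segment_rows]),
        dsc=pd.DataFrame([r for p in results for r in p.dsc_rows]),
        lesions=pd.DataFrame([r for p in results for r in p.lesion_rows]),
        volumes=pd.DataFrame([r for p in results for r in p.volume_rows]),
        config=config,
    )


# ---------------------------------------------------------------------------
# statistics over a cohort result


def _report_to_dict(report: ComparisonReport) -> dict:
    return {
        "conditions": report.conditions,
        "n": report.n,
        "test": report.test,
        "statistic": report.statistic,
        "p_value": report.p_value,
        "alpha": report.alpha,
        "significant": report.significant,
        "degenerate": report.degenerate,
        "n_zero_differences": report.n_zero_differences,
        "normality": {
            k: {"normal": v.normal, "p_value": v.p_value, "degenerate": v.degenerate}
            for k, v in report.normality.items()
        },
        "posthoc": [dataclasses.asdict(p) for p in report.posthoc],
        "summaries": {
            k: (dataclasses.asdict(s) if s is not None else None)
            for k, s in report.summaries.items()
        },
    }


def cohort_statistics(result: CohortResult) -> dict:
    """The full comparison battery over a cohort result.

    Per scheme: pairwise modality comparisons of sensitivity and (where
    enough defined values exist) specificity; per modality: multi-scheme
    sensitivity comparison; plus the DSC modality comparison.  Comparisons
    with too few complete cases are skipped with a reason.
    """
    out: dict = {
        "provenance": {
            "tool": "histoconcord",
            "version": __version__,
            "config_hash": result.config.config_hash,
            "config": result.config.to_dict(),
        },
        "comparisons": {},
    }
    modalities = sorted(result.segments["modality"].unique())
    schemes = [Scheme(s) for s in result.segments["scheme"].unique()]

    def _try(name: str, fn, *args, **kwargs):
        try:
            out["comparisons"][name] = _report_to_dict(fn(*args, **kwargs))
        except ValueError as exc:
            out["comparisons"][name] = {"skipped": True, "reason": str(exc)}

    for scheme in schemes:
        for metric in ("sensitivity", "specificity"):
            table = result._metric_table(metric, scheme)
            for i, a in enumerate(modalities):
                for b in modalities[i + 1 :]:
                    _try(
                        f"{metric}:{scheme.value}:{a}-vs-{b}",
                        compare_two,
                        table,
                        a,
                        b,
                        alpha=result.config.alpha,
                    )
    for modality in modalities:
        table = result.scheme_table("sensitivity", modality)
        present = [s.value for s in ALL_SCHEMES if s.value in table.columns]
        if len(present) >= 3:
            _try(
                f"sensitivity-across-schemes:{modality}",
                compare_many,
                table,
                present,
                alpha=result.config.alpha,
            )
    dsc_table = result.dsc_table()
    for i, a in enumerate(modalities):
        for b in modalities[i + 1 :]:
            _try(f"dsc:{a}-vs-{b}", compare_two, dsc_table, a, b, alpha=result.config.alpha)
    return out


# ---------------------------------------------------------------------------
# disk I/O for cohorts, results and truth tables


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# histoconcord {__version__} config_hash={config.config_hash} "
        f"seed={config.master_seed}\n"
    )


def write_cohort_result(result: CohortResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance_header(result.config)
    for name in ("segments", "dsc", "lesions", "volumes"):
        df: pd.DataFrame = getattr(result, name)
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "tool": "histoconcord",
                "version": __version__,
                "config_hash": result.config.config_hash,
                "config": result.config.to_dict(),
            },
            indent=2,
        )
    )


def read_result_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _json_default(o):
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "patient_id": truth.patient_id,
        "lesions": [dataclasses.asdict(l) for l in truth.lesions],
        "false_positive_counts": truth.false_positive_counts,
        "confusion": {
            f"{scheme}|{modality}": counts
            for (scheme, modality), counts in truth.confusion.items()
        },
        "reference_positivity": truth.reference_positivity,
    }


def save_cohort(
    cohort: list[tuple[StructureSet, PhantomTruth | None]],
    outdir: str | Path,
    master_seed: int | None = None,
) -> list[Path]:
    """Write a phantom cohort to disk: NIfTI masks + per-patient manifest
    + truth tables.  Returns the manifest paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = []
    truth_records = []
    for sset, truth in cohort:
        pdir = outdir / sset.patient_id
        pdir.mkdir(exist_ok=True)
        manifest = {"patient_id": sset.patient_id, "tests": {}}
        for role in ("gland", "reference"):
            path = pdir / f"{role}.nii.gz"
            write_mask(getattr(sset, role), path)
            manifest[role] = str(path.relative_to(pdir))
        for name, mask in sset.tests.items():
            path = pdir / f"{name}.nii.gz"
            write_mask(mask, path)
            manifest["tests"][name] = str(path.relative_to(pdir))
        mpath = pdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        manifests.append(mpath)
        if truth is not None:
            tdict = truth_to_dict(truth)
            (pdir / "truth.json").write_text(
                json.dumps(tdict, indent=2, default=_json_default)
            )
            for lesion in tdict["lesions"]:
                truth_records.append(
                    {
                        "patient_id": sset.patient_id,
                        "lesion_id": lesion["lesion_id"],
                        "analytic_volume_ml": lesion["analytic_volume_ml"],
                        "analytic_diameter_mm": lesion["analytic_diameter_mm"],
                        "feret_diameter_mm": lesion["feret_diameter_mm"],
                        "is_index": lesion["is_index"],
                    }
                )
    if truth_records:
        pd.DataFrame(truth_records).to_csv(outdir / "truth_lesions.csv", index=False)
    if master_seed is not None:
        (outdir / "cohort.json").write_text(
            json.dumps(
                {"master_seed": master_seed, "n_patients": len(cohort)}, indent=2
            )
        )
    return manifests


def load_truth(path: str | Path) -> dict:
    """Load a per-patient truth.json back into the dict form of
    :func:`truth_to_dict`."""
    return json.loads(Path(path).read_text())
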