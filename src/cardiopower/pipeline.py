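"""Protocol orchestration: simulate the full in-silico experiment and
run the complete agreement analysis.

The default protocol per animal is 10 sets of (baseline, reduced
preload, increased afterload) — mechanical interventions first — then 10
measurements each under dobutamine, nitroprusside and metoprolol: 60
measurements of 10 cardiac cycles, i.e. 600 (10 x 10 x 6) paired SW /
power-integral values per animal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement_stats import (
    MixedFitResult,
    bland_altman,
    condition_contrasts,
    fit_mixed_slope_model,
    through_origin_fit,
)
from .beat_metrics import (
    AlphaFactor,
    alpha_calibration,
    beat_summary,
    oscillatory_fraction,
    segment_record,
    stroke_volume_from_conductance,
    stroke_volume_from_flow,
)
from .errors import CalibrationError, DatasetError
from .hemo_sim import (
    AnimalSpec,
    ConditionSpec,
    SimConfig,
    measurement_model,
    sample_animals,
    simulate_record,
)
from .signal_io import WaveformRecord, read_record, write_beat_table, write_record

logger = logging.getLogger("cardiopower")

DRUG_ORDER = ("dobutamine", "nitroprusside", "metoprolol")
MECHANICAL_SET = ("baseline", "preload_reduced", "afterload_increased")


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """Shape of the full experiment."""

    n_animals: int = 6
    n_sets: int = 10
    n_drug_measurements: int = 10
    cycles_per_measurement: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_animals", "n_sets", "n_drug_measurements", "cycles_per_measurement"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def measurement_plan(self) -> list[str]:
        """Condition of each measurement, in acquisition order."""
        plan = []
        for _ in range(self.n_sets):
            plan.extend(MECHANICAL_SET)
        for drug in DRUG_ORDER:
            plan.extend([drug] * self.n_drug_measurements)
        return plan

    @property
    def n_measurements(self) -> int:
        return 3 * self.n_sets + 3 * self.n_drug_measurements


def _measurement_seed(protocol_seed: int, animal_index: int, meas_index: int) -> int:
    ss = np.random.SeedSequence(entropy=[protocol_seed, animal_index, meas_index])
    return int(ss.generate_state(1)[0])


def simulate_protocol(
    spec: ProtocolSpec,
    sim_cfg: SimConfig | None = None,
    animals: Sequence[AnimalSpec] | None = None,
) -> Iterator[WaveformRecord]:
    """Yield the measured records of the whole protocol, in order.

    Two extra cardiac cycles are simulated per measurement: the onset of
    the very first cycle falls on sample 0 where no peak can be detected,
    and cycles need a closing R peak, so ``cycles_per_measurement + 2``
    simulated cycles yield exactly ``cycles_per_measurement`` full R-to-R
    cycles after segmentation.  All randomness derives from ``spec.seed``.
    """
    base_cfg = sim_cfg if sim_cfg is not None else SimConfig()
    if animals is None:
        animals = sample_animals(spec.n_animals, seed=spec.seed)
    for ai, animal in enumerate(animals):
        for mi, cond_name in enumerate(spec.measurement_plan(), start=1):
            cfg = dataclasses.replace(
                base_cfg,
                n_cycles=spec.cycles_per_measurement + 2,
                seed=_measurement_seed(spec.seed, ai, mi),
            )
            true_rec = simulate_record(animal, ConditionSpec.default(cond_name), cfg)
            rec = measurement_model(true_rec, animal, cfg)
            rec.meta["measurement_index"] = mi
            yield rec


def run_protocol(
    spec: ProtocolSpec,
    out_dir,
    sim_cfg: SimConfig | None = None,
) -> list[Path]:
    """Simulate the protocol and write every record to ``out_dir``.

    Layout: ``<out>/animal_<id>/meas_<index>_<condition>.csv`` (+ JSON
    sidecars) and a ``protocol.json`` manifest.  Deterministic under
    ``spec.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in simulate_protocol(spec, sim_cfg=sim_cfg):
        animal_dir = out_dir / f"animal_{rec.meta['animal_id']}"
        animal_dir.mkdir(exist_ok=True)
        name = f"meas_{rec.meta['measurement_index']:03d}_{rec.meta['condition']}.csv"
        path = animal_dir / name
        try:
            write_record(rec, path)
        except OSError as exc:
            raise DatasetError(f"failed writing record {path}: {exc}") from exc
        paths.append(path)
    manifest = {
        "protocol": dataclasses.asdict(spec),
        "n_records": len(paths),
        "version": __version__,
    }
    (out_dir / "protocol.json").write_text(json.dumps(manifest, indent=1))
    logger.info("wrote %d records to %s", len(paths), out_dir)
    return paths


def calibrate_animal(records: Sequence[WaveformRecord]) -> AlphaFactor:
    """Alpha gain for one animal from its baseline records only."""
    pairs = []
    for rec in records:
        if rec.meta.get("condition") != "baseline":
            continue
        for span in segment_record(rec):
            pairs.append(
                (
                    stroke_volume_from_conductance(rec.v_lv, span),
                    stroke_volume_from_flow(rec.q_ao, span, rec.fs),
                )
            )
    if not pairs:
        raise CalibrationError("animal has no baseline measurements; cannot calibrate alpha")
    return alpha_calibration(pairs)


@dataclasses.dataclass
class AgreementResults:
    """Everything the analysis produces for one dataset."""

    beat_table: pd.DataFrame
    per_animal: pd.DataFrame
    conditions: pd.DataFrame
    bland_altman_points: pd.DataFrame
    mixed_fit: MixedFitResult | None
    alphas: dict[str, AlphaFactor]
    oscillatory_fraction_baseline: float
    exclusions: int = 0


def analyze_records(
    records: Sequence[WaveformRecord],
    reference: str = "baseline",
    direction: str = "pwr_on_sw",
    method: str = "reml",
) -> AgreementResults:
    """Full analysis chain on in-memory records.

    Per animal: alpha calibration from baseline, then per-beat summaries,
    a through-origin fit and a Bland-Altman comparison; pooled across
    animals: the random-slope mixed model with per-condition fixed
    slopes.
    """
    if not records:
        raise DatasetError("no records to analyze")
    by_animal: dict[str, list[WaveformRecord]] = {}
    for rec in records:
        by_animal.setdefault(str(rec.meta.get("animal_id", "?")), []).append(rec)

    alphas: dict[str, AlphaFactor] = {}
    tables = []
    osc_fracs = []
    for animal_id, recs in by_animal.items():
        alpha = calibrate_animal(recs)
        alphas[animal_id] = alpha
        for rec in recs:
            spans = segment_record(rec)
            tables.append(beat_summary(rec, spans, alpha))
            if rec.meta.get("condition") == "baseline":
                osc_fracs.append(oscillatory_fraction(rec, spans))
    beat_table = pd.concat(tables, ignore_index=True)

    per_animal_rows = []
    ba_points = []
    for animal_id, sub in beat_table.groupby("animal_id", sort=True):
        sw = sub["sw_J"].to_numpy()
        pwr = sub["pwr_integral_J"].to_numpy()
        x, y = (sw, pwr) if direction == "pwr_on_sw" else (pwr, sw)
        fit = through_origin_fit(x, y)
        ba = bland_altman(sw, pwr)
        per_animal_rows.append(
            {
                "animal_id": animal_id,
                "n_beats": fit.n,
                "alpha": alphas[str(animal_id)].alpha,
                "slope": fit.slope,
                "ci95_low": fit.ci95_low,
                "ci95_high": fit.ci95_high,
                "r2_uncentered": fit.r2_uncentered,
                "pearson_r": fit.pearson_r,
                "ba_mean_diff_J": ba.mean_diff,
                "ba_sd_diff_J": ba.sd_diff,
                "ba_loa_low_J": ba.loa_low,
                "ba_loa_high_J": ba.loa_high,
            }
        )
        ba_points.append(
            pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "condition": sub["condition"].to_numpy(),
                    "mean_J": ba.means,
                    "diff_J": ba.diffs,
                }
            )
        )
    per_animal = pd.DataFrame(per_animal_rows)

    if beat_table["animal_id"].nunique() >= 2:
        mixed = fit_mixed_slope_model(
            beat_table, reference=reference, method=method, direction=direction
        )
        conditions = condition_contrasts(mixed)
        conditions["lrt_p_random_slope"] = mixed.lrt_p_random
    else:
        # random-slope variance is inestimable from one animal
        logger.warning("single animal: skipping the mixed model")
        mixed = None
        conditions = pd.DataFrame(
            columns=["condition", "slope", "ci95_low", "ci95_high",
                     "p_vs_reference", "is_reference", "lrt_p_random_slope"]
        )

    return AgreementResults(
        beat_table=beat_table,
        per_animal=per_animal,
        conditions=conditions,
        bland_altman_points=pd.concat(ba_points, ignore_index=True),
        mixed_fit=mixed,
        alphas=alphas,
        oscillatory_fraction_baseline=float(np.mean(osc_fracs)) if osc_fracs else float("nan"),
    )


def load_dataset(dataset_dir) -> list[WaveformRecord]:
    """Read every waveform record below a dataset directory."""
    dataset_dir = Path(dataset_dir)
    if not dataset_dir.is_dir():
        raise DatasetError(f"dataset directory not found: {dataset_dir}")
    files = sorted(p for p in dataset_dir.rglob("meas_*.csv") if not p.name.endswith(".meta.json"))
    if not files:
        raise DatasetError(f"no waveform records found under {dataset_dir}")
    return [read_record(p) for p in files]


def analyze_dataset(
    dataset_dir,
    out_dir,
    reference: str = "baseline",
    direction: str = "pwr_on_sw",
    method: str = "reml",
) -> AgreementResults:
    """Load, analyze, and write the result tables.

    Outputs under ``out_dir``: ``beat_table.csv``, ``per_animal.csv``
    (per-animal slopes/correlations/Bland-Altman), ``conditions.csv``
    (mixed-model slopes per condition), ``bland_altman.csv`` (point sets)
    and ``run_log.txt``.
    """
    records = load_dataset(dataset_dir)
    results = analyze_records(records, reference=reference, direction=direction, method=method)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_beat_table(results.beat_table, out_dir / "beat_table.csv")
    results.per_animal.to_csv(out_dir / "per_animal.csv", index=False, float_format="%.6g")
    results.conditions.to_csv(out_dir / "conditions.csv", index=False, float_format="%.6g")
    results.bland_altman_points.to_csv(
        out_dir / "bland_altman.csv", index=False, float_format="%.6g"
    )
    seeds = sorted({rec.meta.get("seed") for rec in records if "seed" in rec.meta})
    log_lines = [
        f"cardiopower {__version__}",
        f"dataset: {Path(dataset_dir).resolve()}",
        f"records: {len(records)}",
        f"beats: {len(results.beat_table)}",
        f"animals: {sorted(results.alphas)}",
        f"alphas: { {k: round(v.alpha, 6) for k, v in results.alphas.items()} }",
        f"direction: {direction}  reference: {reference}  method: {method}",
        "mixed model converged: "
        + (str(results.mixed_fit.converged) if results.mixed_fit else "skipped (single animal)"),
        f"excluded records: {results.exclusions}",
        f"record seeds (first 5): {seeds[:5]}",
    ]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("analysis written to %s", out_dir)
    return results
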