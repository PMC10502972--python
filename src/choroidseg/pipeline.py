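"""End-to-end orchestration: simulate phantoms, train, evaluate, measure
SfChT, and run the cohort statistics from one declarative config with a
single global seed.

Every stage derives its own seed deterministically from the global seed
(via ``numpy.random.SeedSequence.spawn``), so an identical config yields
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cohort import (
    CohortSpec, adjusted_group_change, change_from_baseline,
    hierarchical_regression, pearson_r, simulate_cohort,
)
from .nn.models import NetworkConfig, build_network, save_checkpoint
from .phantom import PhantomSpec, generate_phantom, generate_scan_set
from .postprocess import clean_mask, measure_sfcht
from .train_eval import TrainConfig, evaluate, predict_probability, train

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration for the demo pipeline."""

    out_dir: str = "choroidseg_run"
    seed: int = 0
    n_train: int = 30
    n_eval: int = 10
    preset: str = "tiny"
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 3e-3
    architecture: str = "unet"
    cohort_n_dims: int = 78
    cohort_n_sv: int = 80

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _make_spec(preset: str, rng: np.random.Generator) -> PhantomSpec:
    maker = PhantomSpec.tiny if preset == "tiny" else PhantomSpec.full
    max_shift = 8 if preset == "tiny" else 10
    return maker(
        pit_shift=int(rng.integers(-max_shift, max_shift + 1)),
        choroid_px=int(rng.integers(10, 19) if preset == "tiny"
                       else rng.integers(55, 90)),
        seed=int(rng.integers(2**31 - 1)),
    )


def make_phantom_dataset(n: int, preset: str, seed: int):
    """n independent phantoms with randomized pit position and choroid
    thickness, each paired with its exact ground-truth mask."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = _make_spec(preset, rng)
        out.append(generate_phantom(spec) + (spec,))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → train → evaluate → measure → cohort-stats.

    Returns a dict of the key artifacts and writes CSV/JSON outputs under
    ``config.out_dir``.  Fully deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    seed_of = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    artifacts: dict = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        train_set = [(b, m) for b, m, _ in make_phantom_dataset(
            config.n_train, config.preset, seed_of[0])]
        eval_full = make_phantom_dataset(config.n_eval, config.preset,
                                         seed_of[1])
        eval_set = [(b, m) for b, m, _ in eval_full]
    except Exception as err:
        raise RuntimeError(f"[simulate] {err}") from err

    try:
        stage("train")
        net_cfg = (NetworkConfig.tiny if config.preset == "tiny"
                   else NetworkConfig.paper)(
            architecture=config.architecture, seed=seed_of[2])
        model = build_network(net_cfg)
        tcfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                           learning_rate=config.learning_rate,
                           seed=seed_of[2])
        model, history = train(model, train_set, tcfg)
        ckpt = out / "model.npz"
        save_checkpoint(model, ckpt)
        (out / "train_log.txt").write_text(
            "".join(f"epoch {i + 1} dice_loss {loss:.6f}\n"
                    for i, loss in enumerate(history)))
        artifacts["loss_history"] = history
    except Exception as err:
        raise RuntimeError(f"[train] {err}") from err

    try:
        stage("evaluate")
        report = evaluate(model, eval_set)
        pd.DataFrame(report.per_image,
                     columns=["image", "dsc", "assd_px"]).to_csv(
            out / "eval_report.csv", index=False)
        artifacts["eval_summary"] = report.summary()
    except Exception as err:
        raise RuntimeError(f"[evaluate] {err}") from err

    try:
        stage("measure")
        measurements = []
        for i, (_, _, spec) in enumerate(eval_full[:3]):
            scans = generate_scan_set(spec, jitter_seed=seed_of[3] + i)
            seg_scans = [
                (b, clean_mask(predict_probability(model, b.pixels)))
                for b, _ in scans]
            m = measure_sfcht(seg_scans, subject=f"P{i:02d}", visit="demo")
            measurements.append(m)
        cio.write_measurements(measurements, out / "measurements.csv")
        artifacts["measurements"] = measurements
    except Exception as err:
        raise RuntimeError(f"[measure] {err}") from err

    try:
        stage("cohort-stats")
        spec = CohortSpec(n_dims=config.cohort_n_dims,
                          n_sv=config.cohort_n_sv, seed=seed_of[4])
        cohort = simulate_cohort(spec)
        cohort.to_csv(out / "cohort.csv", index=False, float_format="%.4f")
        stats = compute_cohort_report(cohort)
        (out / "cohort_report.json").write_text(json.dumps(stats, indent=2))
        artifacts["cohort_report"] = stats
    except Exception as err:
        raise RuntimeError(f"[cohort-stats] {err}") from err

    return artifacts


def compute_cohort_report(cohort: pd.DataFrame) -> dict:
    """The standard longitudinal analysis on one cohort table: adjusted
    group changes per visit, the 24-month ΔSfChT–ΔAL association, and the
    hierarchical regression of 12-month elongation on early choroidal
    change."""
    changes = change_from_baseline(cohort)
    report: dict = {"visits": {}}
    for visit in changes["visit"].unique():
        sub = changes[changes["visit"] == visit]
        report["visits"][visit] = adjusted_group_change(
            sub["d_sfcht"].to_numpy(), sub["baseline_sfcht"].to_numpy(),
            sub["group"].to_numpy())
    m24 = changes[changes["visit"] == "24m"].dropna(
        subset=["d_axial_length"])
    report["pearson_dsfcht_dal_24m"] = pearson_r(
        m24["d_sfcht"], m24["d_axial_length"])
    wide = _wide_for_regression(changes)
    hier = hierarchical_regression(wide, outcome="d_al_12m",
                                   candidate="d_sfcht_3m")
    report["hierarchical_regression"] = {
        "r2_base": hier.r2_base, "r2_full": hier.r2_full,
        "delta_r2": hier.delta_r2, "betas": hier.betas_full,
        "p_values": hier.pvalues_full, "n": hier.n,
    }
    return report


def _wide_for_regression(changes: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: age, gender, early choroid changes, and the
    12-month axial elongation."""
    first = changes.drop_duplicates("subject").set_index("subject")
    wide = first[["age", "gender", "group"]].copy()
    for visit in ("1w", "1m", "3m"):
        sub = changes[changes["visit"] == visit].set_index("subject")
        wide[f"d_sfcht_{visit}"] = sub["d_sfcht"]
    sub12 = changes[changes["visit"] == "12m"].set_index("subject")
    wide["d_al_12m"] = sub12["d_axial_length"]
    return wide.reset_index()
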