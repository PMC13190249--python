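"""End-to-end orchestration: simulate -> preprocess -> spectral -> units ->
phaselock -> groupstats, from a single config with deterministic seeding.

One global seed is expanded into per-stage sub-seeds with
``numpy.random.SeedSequence(seed).spawn``, so any stage can be rerun in
isolation with its own stream.  Every output file is checksummed into a
run manifest; rerunning the same config reproduces the checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import spectral, units as units_mod
from .groupstats import compare_groups
from .io import load_recording, load_spike_trains, load_waveforms
from .phaselock import lock_unit, locked_proportion_test, morlet_phase
from .preprocess import condition_lfp
from .synthdata import CohortSpec, GroupSpec, SynthConfig, generate_cohort

__all__ = ["RunConfig", "PipelineStageError", "run"]


class PipelineStageError(RuntimeError):
    """A named pipeline stage failed; earlier stage outputs are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    cohort: CohortSpec | None = None
    input_dir: str | None = None
    band: tuple[float, float] = (3.0, 5.0)
    n_shuffle: int = 100
    seed: int = 0
    do_spectral: bool = True
    do_units: bool = True
    do_phaselock: bool = True
    do_groupstats: bool = True

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise ValueError("either a cohort spec or an input directory is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            base = SynthConfig(**cohort.pop("base", {}))
            groups = [GroupSpec(**g) for g in cohort.pop("groups")]
            cohort = CohortSpec(groups=groups, base=base,
                                seed=cohort.get("seed", raw.get("seed", 0)))
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(cohort=cohort, **raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.suffix == ".h5":
        # hash dataset contents, not container bytes (HDF5 stores timestamps)
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
            f.visititems(visit)
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_config_dict(config), indent=1))
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(["simulate", "shuffle"], ss.spawn(2)))
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    # -- simulate / locate inputs ------------------------------------------
    if config.cohort is not None:
        data_dir = out / "cohort"
        try:
            cohort_manifest = generate_cohort(config.cohort, data_dir)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("simulate", e) from e
        manifest["stages"].append("simulate")
    else:
        data_dir = Path(config.input_dir)
        with open(data_dir / "manifest.json") as f:
            cohort_manifest = json.load(f)

    subjects = cohort_manifest["subjects"]

    # -- spectral -----------------------------------------------------------
    coh_df = None
    if config.do_spectral:
        try:
            rows = []
            shuffle_rng = np.random.default_rng(stage_seeds["shuffle"])
            for sub in subjects:
                rec_a = condition_lfp(load_recording(data_dir / sub["files"]["regionA"]))
                rec_b = condition_lfp(load_recording(data_dir / sub["files"]["regionB"]))
                conf = spectral.shuffle_confidence(
                    rec_a, rec_b, n_iter=config.n_shuffle, rng=shuffle_rng)
                res = spectral.msc(rec_a, rec_b, conf_limit=conf)
                auc = spectral.band_auc(res, *config.band)
                in_band = (res.freqs >= config.band[0]) & (res.freqs <= config.band[1])
                rows.append({"subject": sub["subject"], "group": sub["group"],
                             "band_auc": auc,
                             "frac_above_conf": float(np.mean(
                                 res.msc[in_band] > conf[in_band])),
                             "n_windows": res.n_windows})
            coh_df = pd.DataFrame(rows)
            coh_df.to_csv(out / "coherence.csv", index=False)
            manifest["stages"].append("spectral")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("spectral", e) from e

    # -- units --------------------------------------------------------------
    units_df = None
    if config.do_units:
        try:
            rows = []
            for sub in subjects:
                dur = SynthConfig(**cohort_manifest["base_config"]).duration
                trains = load_spike_trains(data_dir / sub["files"]["spikes"], dur)
                wfs = {w.unit_id: w for w in
                       load_waveforms(data_dir / sub["files"]["waveforms"])}
                for i, tr in enumerate(trains):
                    wf = wfs.get(f"u{i}")
                    m = units_mod.compute_unit_metrics(tr, wf)
                    rows.append({"subject": sub["subject"], "group": sub["group"],
                                 "unit_id": m.unit_id, "mean_rate": m.mean_rate,
                                 "fano": m.fano, "valley_to_peak_ms": m.valley_to_peak_ms,
                                 "fwhm_ms": m.fwhm_ms, "cell_class": m.cell_class})
            units_df = pd.DataFrame(rows)
            units_df.to_csv(out / "unit_metrics.csv", index=False)
            manifest["stages"].append("units")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("units", e) from e

    # -- phaselock ----------------------------------------------------------
    lock_df = None
    if config.do_phaselock:
        try:
            rows = []
            for sub in subjects:
                spikes_path = data_dir / sub["files"]["spikes"]
                if not spikes_path.exists():
                    raise FileNotFoundError(spikes_path)
                rec_a = condition_lfp(load_recording(data_dir / sub["files"]["regionA"]))
                phases = morlet_phase(rec_a)
                dur = rec_a.duration
                for tr in load_spike_trains(spikes_path, dur):
                    r = lock_unit(tr, phases)
                    rows.append({"subject": sub["subject"], "group": sub["group"],
                                 "unit_id": r.unit_id, "locked": r.locked,
                                 "best_freq": r.best_freq,
                                 "preferred_angle_deg": r.preferred_angle_deg,
                                 "resultant_length": r.resultant_length,
                                 "n_spikes": r.n_spikes,
                                 "min_p": float(np.nanmin(r.p_values))
                                 if np.any(np.isfinite(r.p_values)) else np.nan,
                                 "excluded": r.excluded_reason or ""})
            lock_df = pd.DataFrame(rows)
            lock_df.to_csv(out / "locking.csv", index=False)
            groups = sorted(lock_df["group"].unique())
            summaries = {}
            for g in groups:
                sel = lock_df[(lock_df["group"] == g) & (lock_df["excluded"] == "")]
                summaries[g] = {
                    "n_locked": int(sel["locked"].sum()),
                    "n_total": int(len(sel)),
                }
            (out / "locking_groups.json").write_text(json.dumps(summaries, indent=1))
            manifest["stages"].append("phaselock")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("phaselock", e) from e

    # -- groupstats ---------------------------------------------------------
    if config.do_groupstats:
        try:
            comps = []
            groups = sorted({s["group"] for s in subjects})
            if len(groups) >= 2 and coh_df is not None:
                a_vals = coh_df.loc[coh_df["group"] == groups[0], "band_auc"]
                b_vals = coh_df.loc[coh_df["group"] == groups[1], "band_auc"]
                c = compare_groups(a_vals, b_vals, metric="band_auc")
                comps.append(asdict_row(c, groups))
            if len(groups) >= 2 and units_df is not None and len(units_df):
                a_vals = units_df.loc[units_df["group"] == groups[0], "mean_rate"]
                b_vals = units_df.loc[units_df["group"] == groups[1], "mean_rate"]
                if len(a_vals) and len(b_vals):
                    c = compare_groups(a_vals, b_vals, metric="mean_rate")
                    comps.append(asdict_row(c, groups))
            if len(groups) >= 2 and lock_df is not None and len(lock_df):
                ga = lock_df[lock_df["group"] == groups[0]]
                gb = lock_df[lock_df["group"] == groups[1]]
                odds, p = locked_proportion_test(
                    int(ga["locked"].sum()), len(ga),
                    int(gb["locked"].sum()), len(gb))
                comps.append({"metric": "locked_proportion", "groups": str(groups[:2]),
                              "test_used": "fisher", "statistic": odds, "p": p})
            pd.DataFrame(comps).to_csv(out / "comparisons.csv", index=False)
            manifest["stages"].append("groupstats")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("groupstats", e) from e

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _checksum(path)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def asdict_row(c, groups) -> dict:
    d = asdict(c)
    d["groups"] = str(groups[:2])
    return d


def _config_dict(config: RunConfig) -> dict:
    d = {k: v for k, v in config.__dict__.items() if k != "cohort"}
    if config.cohort is not None:
        d["cohort"] = {"seed": config.cohort.seed,
                       "base": asdict(config.cohort.base),
                       "groups": [asdict(g) for g in config.cohort.groups]}
    return d
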