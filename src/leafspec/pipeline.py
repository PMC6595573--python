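"""End-to-end orchestration: simulate/load -> preprocess -> split -> calibrate
-> band search -> evaluate, with one master seed and diffable JSON/CSV outputs.

The master seed deterministically derives one child seed per stage
(simulation, train/test split, CV folds) through numpy's SeedSequence spawn
mechanism, so any stage can be rerun in isolation and repeated runs are
bit-identical. The 60/40 split is computed once per run and shared by every
method and trait, and nothing computed from the test samples feeds back into
any fit or band selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .chemometrics import CVSpec, PLSCalibration, SVRCalibration, DEFAULT_C_GRID
from .evaluate import evaluate_predictions, train_test_split
from .preprocess import PreprocessConfig, preprocess_matrix
from .spectra_io import (
    TraitTable,
    average_replicates,
    read_spectra_csv,
    read_traits_csv,
)
from .vi import VICalibration, builtin_vis, compute_vi, exhaustive_band_search

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("leafspec")

METHODS = ("plsr", "svr", "vi", "band_search")
_STAGES = ("simulate", "split", "cv")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed (< 2**31) from the master seed by a fixed counter."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    child = np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage),))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; synthetic mode when no paths given."""

    spectra_path: str | None = None
    traits_path: str | None = None
    synthetic_config: synthetic.SyntheticConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    methods: tuple[str, ...] = METHODS
    traits: tuple[str, ...] = ("CHL", "LWC", "SLA", "N", "P", "K")
    train_fraction: float = 0.6
    master_seed: int = 0
    cv_k: int = 10
    max_lv: int = 25
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    svr_epsilon: float = 0.1
    output_dir: str = "leafspec_run"

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("trait list must be non-empty")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")
        if self.spectra_path is None and self.synthetic_config is None:
            self.synthetic_config = synthetic.SyntheticConfig()


def _json_dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Writes per-trait, per-method evaluation reports, fitted-model JSON files,
    band-search results, the resolved configuration and a log. Numeric outputs
    are a pure function of the configuration and master seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # ---- data ----
    if config.spectra_path is not None:
        scans = read_spectra_csv(config.spectra_path)
        traits = read_traits_csv(config.traits_path)
        log(f"loaded {len(scans)} scans from {config.spectra_path}")
    else:
        sim_cfg = config.synthetic_config
        sim_cfg.seed = stage_seed(config.master_seed, "simulate")
        scans, traits = synthetic.generate_dataset(sim_cfg)
        log(f"simulated {len(scans)} scans / {len(traits.sample_ids)} plants "
            f"(seed {sim_cfg.seed})")

    matrix = average_replicates(scans)
    log(f"averaged to {matrix.n_samples} samples x {matrix.n_bands} bands")

    processed = preprocess_matrix(matrix, config.preprocess)
    log(f"preprocessed to {processed.n_bands} bands "
        f"({processed.wavelengths_nm[0]:g}-{processed.wavelengths_nm[-1]:g} nm)")

    # ---- split (one split shared by all methods and traits) ----
    split_seed = stage_seed(config.master_seed, "split")
    train_ids, test_ids = train_test_split(
        processed.sample_ids, config.train_fraction, seed=split_seed
    )
    log(f"split {len(train_ids)} train / {len(test_ids)} test (seed {split_seed})")
    id_pos = {sid: i for i, sid in enumerate(processed.sample_ids)}
    tr = np.array([id_pos[s] for s in train_ids])
    te = np.array([id_pos[s] for s in test_ids])
    X_train, X_test = processed.values[tr], processed.values[te]

    cv = CVSpec(k=config.cv_k, seed=stage_seed(config.master_seed, "cv"))

    reports: dict[str, dict[str, dict]] = {}
    for trait in config.traits:
        y_train = traits.values_for(trait, train_ids)
        y_test = traits.values_for(trait, test_ids)
        reports[trait] = {}

        if "plsr" in config.methods:
            res = PLSCalibration(X_train, y_train, max_lv=config.max_lv, cv=cv,
                                 wavelengths_nm=processed.wavelengths_nm,
                                 trait=trait).fit()
            rep = evaluate_predictions(trait, y_test, res.predict(X_test))
            cal = evaluate_predictions(trait, y_train, res.predict(X_train))
            reports[trait]["plsr"] = {
                "test": rep.to_dict(), "calibration": cal.to_dict(),
                "selected_n_lv": res.selected_n_lv,
                "rmse_cv_by_lv": [float(v) for v in res.rmse_cv_by_lv],
            }
            _json_dump(out / f"model_plsr_{trait}.json", {
                "trait": trait, "selected_n_lv": res.selected_n_lv,
                "coefficients_std": [float(v) for v in res.coef_],
                "x_mean": [float(v) for v in res.x_standardizer.mean],
                "x_sd": [float(v) for v in res.x_standardizer.sd],
                "y_mean": float(res.y_standardizer.mean[0]),
                "y_sd": float(res.y_standardizer.sd[0]),
            })
            log(f"{trait} plsr: n_LV={res.selected_n_lv} "
                f"test R2={rep.r2:.3f} RPD={rep.rpd:.2f} ({rep.category})")

        if "svr" in config.methods:
            res = SVRCalibration(X_train, y_train, c_grid=config.c_grid,
                                 epsilon=config.svr_epsilon, cv=cv,
                                 trait=trait).fit()
            rep = evaluate_predictions(trait, y_test, res.predict(X_test))
            cal = evaluate_predictions(trait, y_train, res.predict(X_train))
            reports[trait]["svr"] = {
                "test": rep.to_dict(), "calibration": cal.to_dict(),
                "selected_C": res.C,
                "rmse_cv_by_c": [float(v) for v in res.rmse_cv_by_c],
            }
            _json_dump(out / f"model_svr_{trait}.json", {
                "trait": trait, "C": res.C, "epsilon": res.epsilon,
                "coefficients_std": [float(v) for v in res.coefficient_vector],
                "intercept_std": res.intercept,
                "y_mean": float(res.y_standardizer.mean[0]),
                "y_sd": float(res.y_standardizer.sd[0]),
            })
            log(f"{trait} svr: C={res.C:g} "
                f"test R2={rep.r2:.3f} RPD={rep.rpd:.2f} ({rep.category})")

        if "vi" in config.methods:
            vi_block = {}
            for definition in builtin_vis():
                v_all = compute_vi(processed, definition)
                model = VICalibration(v_all[tr], y_train, definition).fit()
                rep = evaluate_predictions(trait, y_test, model.predict(v_all[te]))
                vi_block[definition.name] = {
                    "test": rep.to_dict(),
                    "bands_nm": [definition.band1_nm, definition.band2_nm],
                    "coefficients": [model.intercept, model.linear_coef,
                                     model.quadratic_coef],
                }
                log(f"{trait} vi {definition.name}: test R2={rep.r2:.3f} "
                    f"RPD={rep.rpd:.2f}")
            reports[trait]["vi"] = vi_block

        if "band_search" in config.methods:
            # search on training samples only; evaluate the winner on the test set
            train_matrix = type(processed)(
                sample_ids=train_ids,
                wavelengths_nm=processed.wavelengths_nm,
                values=X_train,
            )
            search = exhaustive_band_search(train_matrix, y_train)
            best = search.best_definition
            v_all = compute_vi(processed, best)
            model = VICalibration(v_all[tr], y_train, best).fit()
            rep = evaluate_predictions(trait, y_test, model.predict(v_all[te]))
            reports[trait]["band_search"] = {
                "test": rep.to_dict(),
                "bands_nm": [best.band1_nm, best.band2_nm],
                "train_correlation": search.train_correlation,
                "n_pairs_evaluated": search.n_pairs_evaluated,
            }
            log(f"{trait} band_search: bands=({best.band2_nm:g},{best.band1_nm:g}) nm "
                f"r={search.train_correlation:.3f} test R2={rep.r2:.3f}")

        _json_dump(out / f"report_{trait}.json", reports[trait])

    _json_dump(out / "reports.json", reports)
    resolved = {
        "methods": list(config.methods),
        "traits": list(config.traits),
        "train_fraction": config.train_fraction,
        "master_seed": config.master_seed,
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in _STAGES},
        "cv_k": config.cv_k,
        "max_lv": config.max_lv,
        "c_grid": list(config.c_grid),
        "svr_epsilon": config.svr_epsilon,
        "preprocess": vars(config.preprocess),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "n_bands_processed": processed.n_bands,
        "synthetic": config.spectra_path is None,
    }
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
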