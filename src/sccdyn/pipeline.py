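"""Configured end-to-end runs: dFC -> (select) -> learn -> code -> stats ->
spectra -> (classify), with every artifact and parameter recorded.

A run is driven by a single :class:`RunConfig` (loadable from YAML or JSON).
Every random operation consumes an explicit seed from the config, so
re-running the same config reproduces the artifacts bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classification import loocv_classify
from .decomposition import code_subject, learn_group_sccs, reconstruct
from .dfc import concatenate_subjects, sliding_window_dfc
from .io import bandpass_filter, read_roi_timeseries
from .model_selection import grid_search
from .spectral import connectivity_spectra
from .stats import edgewise_group_contrast, group_scc_tmap

logger = logging.getLogger("sccdyn")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    data_dir: str
    out_dir: str = "run"
    tr_seconds: float = 2.0
    window_trs: int = 30
    step_trs: int = 2
    drop_initial: int = 0
    bandpass: bool = False
    k: int = 10
    lambda_: float = 0.1
    seed: int = 0
    select: bool = False
    k_grid: list[int] = field(default_factory=lambda: [2, 4, 6, 8, 10])
    lambda_grid: list[float] = field(default_factory=lambda: [0.05, 0.1])
    labels: list[int] | None = None
    classify: bool = False
    q: float = 0.05
    alpha: float = 0.05
    fdr_scope: str = "per_component"
    standardize: bool = True
    init: str = "normal"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValueError(f"config {path} does not hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _save_tsv(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), delimiter="\t", fmt="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    stage = "load"
    try:
        files = sorted(Path(config.data_dir).glob("*.tsv")) + sorted(
            Path(config.data_dir).glob("*.csv")
        )
        if not files:
            raise ValueError(
                f"no .tsv/.csv time-series files in {config.data_dir}"
            )
        subjects = []
        for f in files:
            ts = read_roi_timeseries(f, tr_seconds=config.tr_seconds)
            if config.drop_initial:
                ts.data = ts.data[config.drop_initial:]
            if config.bandpass:
                ts = bandpass_filter(ts)
            subjects.append(ts)
        logger.info("loaded %d subjects from %s", len(subjects),
                    config.data_dir)

        stage = "dfc"
        stacks = [
            sliding_window_dfc(ts, config.window_trs, config.step_trs)
            for ts in subjects
        ]
        stack = concatenate_subjects(stacks)
        logger.info("dfc: %d windows x %d edges", *stack.data.shape)

        k, lam = config.k, config.lambda_
        if config.select:
            stage = "select"
            grid = grid_search(stacks, config.k_grid, config.lambda_grid,
                               seed=config.seed)
            k, lam = grid.chosen_k, grid.chosen_lambda
            (out / "grid.json").write_text(json.dumps({
                "k_values": grid.k_values,
                "lambda_values": grid.lambda_values,
                "test_error": grid.test_error.tolist(),
                "chosen_k": k, "chosen_lambda": lam,
            }, indent=2))
            logger.info("select: chose k=%d lambda=%g", k, lam)

        stage = "learn"
        dec = learn_group_sccs(stack, k=k, lambda_=lam, seed=config.seed,
                               init=config.init)
        _save_tsv(out / "T.tsv", dec.T)
        _save_tsv(out / "C.tsv", dec.C)
        logger.info("learn: %d iterations, converged=%s", dec.n_iter,
                    dec.converged)

        stage = "code"
        subject_C = []
        for i, wc in enumerate(stacks):
            sub = code_subject(wc, dec.subject_temporal(stack, i), lam)
            subject_C.append(sub.C_i)
            _save_tsv(out / f"{wc.subject_id or f'sub{i}'}_C.tsv", sub.C_i)

        stage = "stats"
        gm = group_scc_tmap(subject_C, q=config.q,
                            fdr_scope=config.fdr_scope)
        _save_tsv(out / "tmap.tsv", gm.thresholded)
        labels = (np.asarray(config.labels, int)
                  if config.labels is not None else None)
        if labels is not None and len(np.unique(labels)) == 2:
            contrast = edgewise_group_contrast(
                [c for c, g in zip(subject_C, labels) if g == 0],
                [c for c, g in zip(subject_C, labels) if g == 1],
                alpha=config.alpha,
            )
            _save_tsv(out / "contrast_t.tsv", contrast.t_values)

        stage = "spectra"
        sub0 = code_subject(stacks[0], dec.subject_temporal(stack, 0), lam)
        rep = connectivity_spectra(stacks[0], reconstruct(sub0))
        _save_tsv(out / "spectra.tsv", np.column_stack([
            rep.freqs, rep.median_power_original,
            rep.median_power_reconstructed, rep.median_power_residual,
        ]))

        result_meta: dict = {}
        if config.classify and labels is not None:
            stage = "classify"
            res = loocv_classify(stacks, labels, k=k, lambda_=lam,
                                 seed=config.seed,
                                 standardize=config.standardize)
            result_meta["classification"] = {
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "predictions": res.fold_predictions.tolist(),
            }

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_hash": config.digest(),
            "version": __version__,
            "k": k, "lambda": lam,
            "n_subjects": len(stacks),
            "edge_order": "upper-triangle-lexicographic-v1",
            **result_meta,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception as e:
        logger.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
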