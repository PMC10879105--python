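"""End-to-end orchestration with manifests, content hashes and fixed seeds.

``run_pipeline`` executes simulate → train/CV → evaluate → bootstrap →
core-system stages into a run directory.  Every stage writes a JSON
manifest recording its parameters, seed and the SHA-256 of each output
file; later stages re-hash the inputs they consume and refuse to run on a
mismatch, so a corrupted or hand-edited intermediate is caught instead of
silently propagated.  Rerunning with an identical config reproduces
identical numerical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, signature, simulate
from .encoding import core_system, structure_coefficients
from .images import (
    ActivationMap,
    BrainMask,
    Volume,
    read_mask,
    read_volume,
    unvectorize,
    vectorize,
    write_volume,
)

__all__ = [
    "run_pipeline",
    "save_beta_series",
    "load_beta_series",
    "save_model",
    "load_model",
    "ManifestError",
]


class ManifestError(RuntimeError):
    """An input artifact does not match the hash recorded at creation time."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _verify_inputs(stage_dir: Path) -> None:
    manifest_path = stage_dir / "manifest.json"
    if not manifest_path.exists():
        raise ManifestError(f"missing manifest for stage directory {stage_dir}")
    manifest = json.loads(manifest_path.read_text())
    for name, digest in manifest["outputs"].items():
        path = stage_dir / name
        if not path.exists():
            raise ManifestError(f"missing artifact {path} required by a later stage")
        if _sha256(path) != digest:
            raise ManifestError(f"hash mismatch for {path}: artifact corrupted or modified")


# ---------------------------------------------------------------------------
# artifact (de)serialization


def save_beta_series(bs: simulate.BetaSeries, out_dir: Path, participant: int) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    nii = out_dir / f"betas_{participant:03d}.nii.gz"
    tsv = out_dir / f"trials_{participant:03d}.tsv"
    data4d = np.zeros(bs.mask.grid.shape + (len(bs.table),))
    flat = data4d.reshape(-1, len(bs.table), order="C")
    flat[bs.mask.indices] = bs.data.T
    write_volume(nii, Volume(bs.mask.grid, data4d))
    bs.table.to_csv(tsv, sep="\t", index=False)
    return [nii, tsv]


def load_beta_series(betas_dir: Path, mask: BrainMask) -> list[simulate.BetaSeries]:
    series = []
    for nii in sorted(Path(betas_dir).glob("betas_*.nii.gz")):
        participant = nii.stem.split(".")[0].split("_")[1]
        table = pd.read_csv(betas_dir / f"trials_{participant}.tsv", sep="\t")
        data = vectorize(read_volume(nii), mask)
        series.append(simulate.BetaSeries(mask=mask, data=np.atleast_2d(data), table=table))
    if not series:
        raise FileNotFoundError(f"no betas_*.nii.gz found in {betas_dir}")
    return series


def save_model(model: signature.SignatureModel, out_dir: Path, name: str = "model") -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    if model.mask is None:
        raise ValueError("model must carry its mask to be serialized")
    nii = out_dir / f"{name}.nii.gz"
    write_volume(nii, Volume(model.mask.grid, unvectorize(model.weights, model.mask)))
    sidecar = out_dir / f"{name}.json"
    sidecar.write_text(
        json.dumps(
            {
                "intercept": model.intercept,
                "config": dataclasses.asdict(model.config),
                "manifest": model.manifest,
                "weights_sha256": _sha256(nii),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [nii, sidecar]


def load_model(model_path: Path, mask: BrainMask) -> signature.SignatureModel:
    model_path = Path(model_path)
    sidecar = json.loads(model_path.with_suffix("").with_suffix(".json").read_text())
    if sidecar["weights_sha256"] != _sha256(model_path):
        raise ManifestError(f"weight image {model_path} does not match its sidecar hash")
    weights = vectorize(read_volume(model_path), mask)
    return signature.SignatureModel(
        weights=weights,
        intercept=float(sidecar["intercept"]),
        mask=mask,
        config=signature.TrainConfig(**sidecar["config"]),
        manifest=sidecar.get("manifest", {}),
    )


def _stack_cohort(series: list[simulate.BetaSeries]):
    maps: list[ActivationMap] = []
    for bs in series:
        maps.extend(simulate.aggregate_by_rating(bs))
    return signature.stack_maps(maps)


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_STAGES = ("simulate", "train", "evaluate", "bootstrap", "core")


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict) or "seed" not in config:
        raise ValueError("config must be a mapping with at least a 'seed' field")
    return config


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run the configured stages into ``out_dir``; returns the summary dict."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg.get("stages", DEFAULT_STAGES))
    summary: dict = {"seed": seed, "stages": stages}

    grid_cfg = cfg.get("grid", {})
    grid = simulate.default_grid(
        shape=tuple(grid_cfg.get("shape", (14, 14, 12))),
        voxel_mm=float(grid_cfg.get("voxel_mm", 3.0)),
    )
    mask = simulate.ellipsoid_mask(grid)
    spec = simulate.SyntheticSpec(seed=seed, **cfg.get("cohort", {}))
    scheme = signature.CVScheme(seed=seed, **cfg.get("cv", {}))
    config_train = signature.TrainConfig(seed=seed, **cfg.get("train", {}))

    sim_dir = out / "simulate"
    if "simulate" in stages:
        series, gt, mask = simulate.simulate_cohort(spec, mask=mask)
        sim_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for p, bs in enumerate(series):
            outputs.extend(save_beta_series(bs, sim_dir, p))
        mask_path = sim_dir / "mask.nii.gz"
        write_volume(mask_path, Volume(grid, mask.to_array().astype(float)))
        truth_path = sim_dir / "ground_truth_anxiety.nii.gz"
        write_volume(truth_path, gt.anxiety_pattern.to_volume())
        outputs += [mask_path, truth_path]
        _write_manifest(sim_dir, "simulate", dataclasses.asdict(spec) | {"mask_voxels": mask.n_voxels}, outputs)
        summary["simulate"] = {"n_participants": spec.n_participants, "n_voxels": mask.n_voxels}

    train_dir = out / "train"
    model = None
    if "train" in stages:
        _verify_inputs(sim_dir)
        mask = read_mask(sim_dir / "mask.nii.gz")
        series = load_beta_series(sim_dir, mask)
        X, y, groups = _stack_cohort(series)
        cv_result = signature.cross_validate(X, y, groups, scheme=scheme, config=config_train)
        model = signature.train(X, y, config=config_train, mask=mask)
        train_dir.mkdir(parents=True, exist_ok=True)
        outputs = save_model(model, train_dir)
        metrics = {
            "cv_overall_r": cv_result.overall_r,
            "cv_evs": cv_result.evs,
            "cv_within_mean_r": cv_result.within_mean_r,
            "n_maps": int(len(y)),
        }
        metrics_path = train_dir / "cv_metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        outputs.append(metrics_path)
        _write_manifest(train_dir, "train", dataclasses.asdict(scheme), outputs)
        summary["train"] = metrics

    if "evaluate" in stages:
        _verify_inputs(train_dir)
        mask = read_mask(sim_dir / "mask.nii.gz")
        model = load_model(train_dir / "model.nii.gz", mask)
        series = load_beta_series(sim_dir, mask)
        X, y, groups = _stack_cohort(series)
        responses = signature.apply_signature(model, X)
        perm = inference.permutation_test_r(
            responses, y, n_perm=int(cfg.get("n_perm", 1000)), seed=seed
        )
        fc = inference.forced_choice(model, X, y, groups)
        eval_dir = out / "evaluate"
        eval_dir.mkdir(parents=True, exist_ok=True)
        metrics = {
            "train_sample_r": perm.observed,
            "permutation_p": perm.p,
            "forced_choice_accuracy": fc.accuracy,
            "forced_choice_d": fc.cohens_d,
            "forced_choice_binomial_p": fc.binomial_p,
        }
        path = eval_dir / "metrics.json"
        path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        _write_manifest(eval_dir, "evaluate", {"n_perm": perm.n_perm}, [path])
        summary["evaluate"] = metrics

    if "bootstrap" in stages:
        _verify_inputs(sim_dir)
        mask = read_mask(sim_dir / "mask.nii.gz")
        series = load_beta_series(sim_dir, mask)
        X, y, groups = _stack_cohort(series)
        n_boot = int(cfg.get("bootstrap", {}).get("n_boot", 200))
        boot = inference.bootstrap_weight_map(
            X, y, groups, config=config_train, n_boot=n_boot, seed=seed, mask=mask
        )
        boot_dir = out / "bootstrap"
        boot_dir.mkdir(parents=True, exist_ok=True)
        zpath = boot_dir / "zmap.nii.gz"
        ppath = boot_dir / "pmap.nii.gz"
        write_volume(zpath, Volume(mask.grid, unvectorize(boot.z, mask)))
        write_volume(ppath, Volume(mask.grid, unvectorize(boot.p, mask, fill=1.0)))
        tsv = boot_dir / "summary.tsv"
        pd.DataFrame(
            {
                "n_voxels_p001": [int(boot.threshold_mask(0.001).sum())],
                "n_voxels_p01": [int(boot.threshold_mask(0.01).sum())],
                "n_redrawn": [boot.n_redrawn],
            }
        ).to_csv(tsv, sep="\t", index=False)
        _write_manifest(boot_dir, "bootstrap", {"n_boot": n_boot}, [zpath, ppath, tsv])
        summary["bootstrap"] = {"n_voxels_p001": int(boot.threshold_mask(0.001).sum())}

    if "core" in stages:
        _verify_inputs(sim_dir)
        mask = read_mask(sim_dir / "mask.nii.gz")
        series = load_beta_series(sim_dir, mask)
        within = signature.train_within_individual(
            series, scheme=signature.CVScheme(n_folds=scheme.n_folds, n_repeats=1, seed=seed),
            config=config_train,
        )
        series_by_participant = {bs.table["participant"].iloc[0]: bs for bs in series}
        weight_stack = np.vstack([w.model.weights for w in within])
        enc_rows = []
        for w in within:
            bs = series_by_participant[w.participant]
            keep = ~bs.table["shock_followed"].to_numpy(dtype=bool)
            enc_rows.append(structure_coefficients(bs.data[keep], w.model.weights).coefficients)
        enc_stack = np.vstack(enc_rows)
        core = core_system(weight_stack, enc_stack, q=float(cfg.get("core_q", 0.05)))
        core_dir = out / "core"
        core_dir.mkdir(parents=True, exist_ok=True)
        cpath = core_dir / "core.nii.gz"
        write_volume(cpath, Volume(mask.grid, unvectorize(core.core.astype(float), mask)))
        _write_manifest(core_dir, "core", {"q": core.q}, [cpath])
        summary["core"] = {"n_core_voxels": int(core.core.sum())}

    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
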