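"""End-to-end orchestration: fixtures -> featurize -> curate -> split ->
select -> train -> predict -> evaluate, with validated configs and
provenance records.

Each stage reads the artifacts of its upstream stage from the run directory,
writes its own outputs plus a provenance JSON (config hash, seeds, input
digests) and fails fast with the name of the missing producing stage when an
upstream artifact is absent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import curation, synthetic
from .metrics import evaluate, report_frame
from .model import AffinityModel
from .nn import ModelConfig, TrainConfig
from .pairs import build_pair_features
from .selection import LassoConfig, SelectionResult, stability_select

STAGES = (
    "fixtures",
    "featurize",
    "curate",
    "split",
    "select",
    "train",
    "predict",
    "evaluate",
)


class FixtureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_compounds: int = 30
    n_proteins: int = 6
    n_pairs: int = 120
    duplicate_rate: float = 0.05
    conflict_rate: float = 0.02
    noise_sd: float = 0.1
    superfamily: str = "kinase"
    atoms_per: int = 40


class FeaturizeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_size: int = 16
    gaussian_width: float = 1.5
    scale_radius: float = 0.7
    n_max: int = 6


class SelectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    keep: int = 120
    repeats: int = 3
    cv_folds: int = 5
    n_alphas: int = 20


class NetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d: int = 32
    heads: int = 4
    n_separate: int = 2
    n_joint: int = 2
    d_ffn: int = 64
    k_periodic: int = 4
    sigma_periodic: float = 0.1
    dropout: float = 0.0


class TrainStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_epochs: int = 25
    patience: int = 10
    batch_size: int = 32
    lr: float = 3e-3
    weight_decay: float = 1e-5
    label_type: str = "pchembl"


class RunConfig(BaseModel):
    """Validated top-level pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "run"
    seed: int = 0
    fixtures: FixtureConfig = FixtureConfig()
    featurize: FeaturizeConfig = FeaturizeConfig()
    select: SelectConfig = SelectConfig()
    net: NetConfig = NetConfig()
    train: TrainStageConfig = TrainStageConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


class MissingArtifactError(FileNotFoundError):
    def __init__(self, path: Path, producing_stage: str):
        super().__init__(
            f"missing artifact {path}; run the '{producing_stage}' stage first"
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _provenance(out: Path, stage: str, cfg: RunConfig, inputs: list[Path]):
    rec = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            cfg.model_dump_json().encode()
        ).hexdigest()[:16],
        "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
    }
    (out / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=1))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(path, producing_stage)
    return path


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Execute exactly one pipeline stage; returns a small result summary."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = globals()[f"_stage_{stage}"]
    result = handler(cfg, out)
    _provenance(out, stage, cfg, result.pop("_inputs", []))
    return result


def run_all(cfg: RunConfig, dry_run: bool = False) -> dict:
    """All stages in order with fail-fast semantics."""
    if dry_run:
        return {"plan": list(STAGES)}
    results = {}
    for stage in STAGES:
        results[stage] = run_stage(stage, cfg)
    return results


# ---- stage implementations ---------------------------------------------------


def _stage_fixtures(cfg: RunConfig, out: Path) -> dict:
    f = cfg.fixtures
    bundle = synthetic.make_bundle(
        n_compounds=f.n_compounds,
        n_proteins=f.n_proteins,
        n_pairs=f.n_pairs,
        seed=cfg.seed,
        duplicate_rate=f.duplicate_rate,
        conflict_rate=f.conflict_rate,
        noise_sd=f.noise_sd,
        superfamily=f.superfamily,
        atoms_per=f.atoms_per,
        featurize_kwargs=cfg.featurize.model_dump(),
    )
    synthetic.write_bundle(bundle, out / "fixtures")
    return {"n_interactions": len(bundle.interactions), "_inputs": []}


def _load_fixtures(out: Path):
    fx = out / "fixtures"
    compounds = pd.read_csv(_require(fx / "compounds.tsv", "fixtures"), sep="\t")
    proteins = pd.read_csv(_require(fx / "proteins.tsv", "fixtures"), sep="\t")
    interactions = pd.read_csv(
        _require(fx / "interactions.tsv", "fixtures"), sep="\t"
    )
    clouds = {}
    from .proteins import parse_structure

    for pid in proteins["protein_id"]:
        pdb = _require(fx / "pdb" / f"{pid}.pdb", "fixtures")
        clouds[pid] = parse_structure(pdb.read_text(), pid).coordinates
    return compounds, proteins, interactions, clouds


def _stage_featurize(cfg: RunConfig, out: Path) -> dict:
    compounds, proteins, interactions, clouds = _load_fixtures(out)
    pairs = interactions[["compound_id", "protein_id"]].drop_duplicates().reset_index(drop=True)
    feats = build_pair_features(
        pairs, compounds, proteins, clouds, **cfg.featurize.model_dump()
    )
    np.savez(
        out / "pair_features.npz",
        compound_continuous=feats.compound_continuous,
        compound_binary=feats.compound_binary,
        protein_continuous=feats.protein_continuous,
        protein_binary=feats.protein_binary,
    )
    pairs.to_csv(out / "pair_index.tsv", sep="\t", index=False)
    (out / "pair_blocks.json").write_text(
        json.dumps({k: list(v) for k, v in feats.layout.offsets.items()})
    )
    return {
        "n_pairs": len(pairs),
        "p": feats.layout.total,
        "_inputs": [out / "fixtures" / "interactions.tsv"],
    }


def _stage_curate(cfg: RunConfig, out: Path) -> dict:
    _, _, interactions, _ = _load_fixtures(out)
    curated = curation.curate(interactions)
    curated.to_csv(out / "curated.tsv", sep="\t", index=False)
    return {
        "n_raw": len(interactions),
        "n_curated": len(curated),
        "_inputs": [out / "fixtures" / "interactions.tsv"],
    }


def _stage_split(cfg: RunConfig, out: Path) -> dict:
    curated = pd.read_csv(_require(out / "curated.tsv", "curate"), sep="\t")
    spec = curation.split_train_test(curated, seed=cfg.seed)
    spec.train.to_csv(out / "train.tsv", sep="\t", index=False)
    spec.test.to_csv(out / "test.tsv", sep="\t", index=False)
    scen = curation.assign_validation_scenarios(spec.train, spec.test)
    test_with = spec.test.copy()
    test_with["scenario"] = scen.to_numpy()
    test_with.to_csv(out / "test_scenarios.tsv", sep="\t", index=False)
    return {
        "n_train": len(spec.train),
        "n_test": len(spec.test),
        "_inputs": [out / "curated.tsv"],
    }


def _pair_features_for(out: Path, table: pd.DataFrame):
    from .pairs import PairFeatures, PairLayout

    idx_tab = pd.read_csv(_require(out / "pair_index.tsv", "featurize"), sep="\t")
    with np.load(_require(out / "pair_features.npz", "featurize")) as z:
        blocks = {k: z[k] for k in z.files}
    key = {(c, p): i for i, (c, p) in enumerate(
        zip(idx_tab["compound_id"], idx_tab["protein_id"])
    )}
    rows = np.array(
        [key[(c, p)] for c, p in zip(table["compound_id"], table["protein_id"])]
    )
    layout = PairLayout(
        n_cc=blocks["compound_continuous"].shape[1],
        n_cb=blocks["compound_binary"].shape[1],
        n_pc=blocks["protein_continuous"].shape[1],
        n_pb=blocks["protein_binary"].shape[1],
    )
    return PairFeatures(
        compound_continuous=blocks["compound_continuous"][rows],
        compound_binary=blocks["compound_binary"][rows],
        protein_continuous=blocks["protein_continuous"][rows],
        protein_binary=blocks["protein_binary"][rows],
        layout=layout,
    )


def _stage_select(cfg: RunConfig, out: Path) -> dict:
    train_tab = pd.read_csv(_require(out / "train.tsv", "split"), sep="\t")
    feats = _pair_features_for(out, train_tab)
    X = feats.concatenated()
    y = train_tab["dtp_score"].to_numpy(dtype=float)
    lcfg = LassoConfig(
        keep=cfg.select.keep,
        repeats=cfg.select.repeats,
        cv_folds=cfg.select.cv_folds,
        n_alphas=cfg.select.n_alphas,
        seed=cfg.seed,
    )
    res = stability_select(X, y, lcfg, feats.layout.subfamily_indices)
    payload = {
        "final_mask": res.final_mask.tolist(),
        "always_kept": res.always_kept.tolist(),
        "frequency": res.frequency.tolist(),
        "mean_abs_coef": res.mean_abs_coef.tolist(),
        "repeats": res.repeats,
    }
    (out / "selection.json").write_text(json.dumps(payload))
    return {
        "n_selected": len(res.final_mask),
        "_inputs": [out / "train.tsv", out / "pair_features.npz"],
    }


def _load_selection(out: Path) -> SelectionResult:
    payload = json.loads(_require(out / "selection.json", "select").read_text())
    return SelectionResult(
        frequency=np.array(payload["frequency"]),
        mean_abs_coef=np.array(payload["mean_abs_coef"]),
        final_mask=np.array(payload["final_mask"], dtype=int),
        always_kept=np.array(payload["always_kept"], dtype=int),
        repeats=payload["repeats"],
    )


def _stage_train(cfg: RunConfig, out: Path) -> dict:
    train_tab = pd.read_csv(_require(out / "train.tsv", "split"), sep="\t")
    feats = _pair_features_for(out, train_tab)
    selection = _load_selection(out)
    model = AffinityModel(
        train_tab,
        feats,
        label_type=cfg.train.label_type,
        selection=selection,
        config=ModelConfig(seed=cfg.seed, **cfg.net.model_dump()),
    )
    tcfg = TrainConfig(seed=cfg.seed, **cfg.train.model_dump())
    results = model.fit(tcfg)
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(exist_ok=True)
    for i, ckpt in enumerate(results.ensemble.checkpoints):
        ckpt.save(ckpt_dir / f"ckpt_{i}")
    with open(out / "training_log.jsonl", "w") as f:
        for rec in results.log:
            f.write(json.dumps(rec) + "\n")
    (out / "summary.txt").write_text(results.summary() + "\n")
    import pickle

    (out / "results.pkl").write_bytes(pickle.dumps(results))
    return {
        "epochs": results.n_epochs,
        "best_holdout_loss": results.ensemble.checkpoints[0].holdout_loss,
        "_inputs": [out / "train.tsv", out / "selection.json"],
    }


def _stage_predict(cfg: RunConfig, out: Path) -> dict:
    import pickle

    results = pickle.loads(_require(out / "results.pkl", "train").read_bytes())
    test_tab = pd.read_csv(_require(out / "test_scenarios.tsv", "split"), sep="\t")
    feats = _pair_features_for(out, test_tab)
    pred = results.predict_activity(feats)
    merged = pd.concat([test_tab.reset_index(drop=True), pred], axis=1)
    merged.to_csv(out / "predictions.tsv", sep="\t", index=False)
    return {"n_predictions": len(merged), "_inputs": [out / "results.pkl"]}


def _stage_evaluate(cfg: RunConfig, out: Path) -> dict:
    pred = pd.read_csv(_require(out / "predictions.tsv", "predict"), sep="\t")
    label = cfg.train.label_type
    reports = evaluate(
        pred[label].to_numpy(),
        pred["prediction"].to_numpy(),
        group_by=pred["scenario"].to_numpy() if "scenario" in pred else None,
    )
    overall = evaluate(pred[label].to_numpy(), pred["prediction"].to_numpy())
    frame = report_frame(overall + reports)
    frame.to_csv(out / "metrics.tsv", sep="\t", index=False)
    return {
        "report": frame.to_dict(orient="records"),
        "_inputs": [out / "predictions.tsv"],
    }
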