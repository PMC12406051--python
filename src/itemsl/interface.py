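"""Configuration, ROI decoding and the end-to-end pipeline.

`run_pipeline` ties the stages together: event tables -> trial-wise designs
-> amplitude estimation -> decoding (ROI or searchlight) -> TSV/JSON/NIfTI
artifacts plus a manifest recording versions, the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .decoding import ItemModel
from .design import TransformationMatrix, build_transformation_matrix, build_trialwise_design, read_events_tsv
from .estimators import TrialEstimates, lsa_estimate, lss_estimate
from .searchlight import build_searchlight_index, performance_map_to_image, read_volume, run_searchlight
from .simulation import SimulationConfig, run_method_comparison

__all__ = ["RunConfig", "load_config", "run_pipeline", "roi_decode", "mask_to_columns"]

log = logging.getLogger("itemsl")


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    ``mode`` selects between a simulation study ("simulation") and decoding
    of volumetric data ("empirical").  Empirical runs list one events TSV
    and one 4-D data NIfTI per session plus a 3-D mask.
    """

    mode: str = "simulation"
    output_dir: str = "itemsl_out"
    seed: int = 0
    # --- empirical inputs ---
    events: list[str] = field(default_factory=list)
    data: list[str] = field(default_factory=list)
    mask: str | None = None
    tr: float = 2.0
    estimator: str = "LSA"
    task: str = "classification"
    targets: list[str] = field(default_factory=list)
    modulators: list[str] = field(default_factory=list)
    decode: str = "searchlight"  # or "roi"
    roi_mask: str | None = None
    radius_mm: float = 6.0
    use_reml: bool = True
    # --- simulation options ---
    simulation: dict = field(default_factory=dict)
    n_sims: int = 100
    methods: list[str] = field(default_factory=lambda: ["LSA", "LSS", "ITEM", "FRACRIDGE"])
    log_level: str = "INFO"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return RunConfig(**raw)


def mask_to_columns(analysis_mask: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Column indices (in in-mask enumeration order) of ROI voxels."""
    analysis_mask = np.asarray(analysis_mask, bool)
    roi_mask = np.asarray(roi_mask, bool)
    if analysis_mask.shape != roi_mask.shape:
        raise ValueError("ROI and analysis mask grids differ")
    cols = np.flatnonzero(roi_mask[analysis_mask])
    if cols.size == 0:
        raise ValueError("ROI contains no in-mask voxels")
    return cols


def roi_decode(
    estimates: TrialEstimates,
    roi_columns: np.ndarray,
    T: TransformationMatrix,
    task: str = "classification",
    metric: str | None = None,
    use_reml: bool = True,
    allow_pinv: bool = False,
):
    """Single cross-validated ITEM decoding over all ROI voxels.

    Returns the pooled metric value (classification) or a dict of values
    per parametric target column (regression), matching the scoring used
    for each searchlight.
    """
    roi_columns = np.asarray(roi_columns, int)
    if roi_columns.size == 0:
        raise ValueError("empty ROI")
    sub = estimates.subset_voxels(roi_columns)
    res = ItemModel(sub, T, use_reml=use_reml, allow_pinv=allow_pinv).fit()
    if task == "classification":
        if (metric or "DA").upper() == "BA":
            return res.balanced_accuracy()
        return res.accuracy()
    wanted = [
        n for n, k in zip(T.column_names, T.column_kind) if k == "parametric"
    ]
    if (metric or "CC").upper() == "MAE":
        return {n: res.mae(n) for n in wanted}
    return {n: res.correlation(n) for n in wanted}


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write artifacts to ``config.output_dir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
    }
    try:
        if config.mode == "simulation":
            t0 = _stage("simulation")
            cfg = SimulationConfig(**config.simulation)
            df = run_method_comparison(
                cfg, tuple(config.methods), config.n_sims, config.seed
            )
            df.to_csv(out / "accuracies.tsv", sep="\t", index=False)
            summary = (
                df.groupby("method")["accuracy"].agg(["mean", "median", "std"]).to_dict("index")
            )
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            manifest["stages"].append({"simulation": time.time() - t0})
            manifest["results"] = summary
        elif config.mode == "empirical":
            manifest.update(_run_empirical(config, out, manifest))
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except Exception as exc:  # tag the failing stage for the caller
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_empirical(config: RunConfig, out: Path, manifest: dict) -> dict:
    if not config.events or not config.data or config.mask is None:
        raise ValueError("empirical mode needs events, data and mask paths")
    t0 = _stage("load")
    mask, affine = read_volume(config.mask)
    mask = mask > 0
    blocks = []
    T_blocks = []
    for s, (ev_path, dat_path) in enumerate(zip(config.events, config.data)):
        events = read_events_tsv(ev_path, session=s, modulators=config.modulators)
        data, _ = read_volume(dat_path, match_affine=affine)
        signal = data[mask].T  # scans x in-mask voxels
        design = build_trialwise_design(events, signal.shape[0], config.tr)
        t1 = _stage(f"estimate session {s} ({config.estimator})")
        est_fn = {"LSA": lsa_estimate, "LSS": lss_estimate}.get(config.estimator.upper())
        if est_fn is None:
            if config.estimator.upper() == "FRACRIDGE":
                raise ValueError("fracridge estimation requires the multi-session API")
            raise ValueError(f"unknown estimator {config.estimator!r}")
        blocks.append(est_fn(signal, design, session_id=s))
        T_blocks.append(build_transformation_matrix(events, design))
        manifest["stages"].append({f"estimate_{s}": time.time() - t1})
    estimates = TrialEstimates.concatenate(blocks)
    T = TransformationMatrix(
        np.vstack([b.matrix for b in T_blocks]),
        T_blocks[0].column_names,
        T_blocks[0].column_kind,
    )
    t2 = _stage(f"decode ({config.decode})")
    results: dict = {}
    if config.decode == "roi":
        roi, _ = read_volume(config.roi_mask, match_affine=affine)
        cols = mask_to_columns(mask, roi > 0)
        results["roi"] = roi_decode(
            estimates, cols, T, task=config.task, use_reml=config.use_reml
        )
    else:
        vs = np.abs(np.diag(affine)[:3])
        index = build_searchlight_index(mask, config.radius_mm, tuple(vs))
        maps = run_searchlight(
            estimates, index, T, task=config.task,
            targets=config.targets or None, use_reml=config.use_reml,
        )
        import nibabel as nib

        for name, pmap in maps.items():
            fname = out / f"map_{pmap.metric}_{name}.nii"
            nib.save(performance_map_to_image(pmap, affine), str(fname))
            results[name] = str(fname)
    manifest["stages"].append({"decode": time.time() - t2})
    return {"results": results}


def _versions() -> dict:
    import nibabel
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "itemsl": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "nibabel": nibabel.__version__,
        "sklearn": sklearn.__version__,
    }
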