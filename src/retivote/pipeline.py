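"""End-to-end vessel segmentation pipeline.

Stage order (each intermediate is retained in the result):

1. ``I_green``  — green channel, inverted by default so vessels are the
   bright structure both branches respond to.
2. ``I_Gabor``  — orientation-maximum Gabor response, rescaled to [0, 1].
3. ``I_vessel`` — main gray-voting pass on the (inverted) green channel,
   min-max rescaled to [0, 1]. Vessel centers collect negative votes and
   map near 0, so the fusion factor (1 - I_vessel) is largest on vessels.
4. ``I_gv``     — fusion I_Gabor * (1 - I_vessel).
5. ``I_GMM``    — vessel layer of the K-component intensity GMM fitted
   to the in-FOV pixels of I_gv.
6. ``I_c``      — complement gray-voting pass (k < 0, max_max weights)
   on I_gv; vessels carry strongly negative vote mass.
7. ``I_com``    — binarized complement image (Otsu on -I_c, so the
   vessel class is True).
8. ``I_C_GMM``  — complementation: small-vessel fragments of I_com
   adopted under broken I_GMM seeds.
9. ``I_FINAL``  — squareness-rate fragment elimination.

Every stage is a pure function of (input image, config), with the single
global seed driving the K-means initialization of the GMM — the only
stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .evaluate import confusion, metrics
from .gabor import GaborParams, orientation_max
from .gmm import IntensityGMM, select_vessel_cluster
from .grayvote import (
    K_COMPLEMENT,
    K_MAIN,
    GrayVoteParams,
    binarize,
    fuse,
    gray_vote,
    rescale01,
)
from .postprocess import (
    ComplementParams,
    EliminationParams,
    complement_vessels,
    eliminate_fragments,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("retivote")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the published settings
    (m=11, k=3 main / k=-5 complement on the 0-255 scale, a=3,
    orientations 0..170 step 10, T_seed=30, T_fragment=100,
    size_cut=14000, squareness_cut=0.2)."""

    # io
    fov_mode: str = "restrict"      # "restrict" or "full"
    invert_green: bool = True
    # gabor
    gabor: GaborParams = field(default_factory=GaborParams)
    # gray voting
    grayvote_m: int = 11
    k_main: float = K_MAIN
    k_complement: float = K_COMPLEMENT
    binarize_method: str = "otsu"
    # gmm
    gmm_components: int = 4
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 500
    vessel_rule: str = "brightest_major"
    weighted_assign: bool = True
    # postprocessing
    post: ComplementParams = field(default_factory=ComplementParams)
    elimination: EliminationParams = field(default_factory=EliminationParams)
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fov_mode not in ("restrict", "full"):
            raise ValueError("fov_mode must be 'restrict' or 'full'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "gabor" in d and isinstance(d["gabor"], dict):
            g = dict(d["gabor"])
            if "k0" in g:
                g["k0"] = tuple(g["k0"])
            d["gabor"] = GaborParams(**g)
        if "post" in d and isinstance(d["post"], dict):
            d["post"] = ComplementParams(**d["post"])
        if "elimination" in d and isinstance(d["elimination"], dict):
            d["elimination"] = EliminationParams(**d["elimination"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["gabor"]["k0"] = list(d["gabor"]["k0"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        d = self.to_dict()
        d["gabor"]["k0"] = list(d["gabor"]["k0"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-10s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(
    image,
    config: PipelineConfig | None = None,
    fov: np.ndarray | None = None,
    save_dir=None,
) -> dict:
    """Run the full segmentation on an RGB image (array or path).

    Returns a dict with every intermediate (keys as in the module
    docstring), the FOV actually used, and a ``manifest`` recording the
    config hash, seed and stage summaries. With ``save_dir`` set, all
    intermediates are written there (masks as 0/255 PNG, real-valued
    stages as 32-bit TIFF).
    """
    config = config or PipelineConfig()
    if isinstance(image, (str, Path)):
        rgb = io_formats.read_image(image)
        source = str(image)
    else:
        rgb = np.asarray(image, dtype=np.float64)
        source = "<array>"
    green = io_formats.green_channel(rgb)

    if fov is None and config.fov_mode == "restrict":
        fov = io_formats.estimate_fov(rgb.mean(axis=2))
    fov_used = fov if config.fov_mode == "restrict" else None

    t0 = time.perf_counter()
    i_green = 1.0 - green if config.invert_green else green
    if fov_used is not None:
        i_green = np.where(fov_used, i_green, 0.0)
    t0 = _stage("green", t0)

    i_gabor = orientation_max(i_green, config.gabor, fov=fov_used, rescale=True)
    t0 = _stage("gabor", t0)

    vote_raw = gray_vote(
        i_green, GrayVoteParams(m=config.grayvote_m, k=config.k_main), fov=fov_used
    )
    i_vessel = rescale01(vote_raw, fov=fov_used)
    t0 = _stage("vote", t0)

    i_gv = fuse(i_gabor, i_vessel)
    t0 = _stage("fuse", t0)

    sel = fov_used if fov_used is not None else np.ones(green.shape, bool)
    values = i_gv[sel]
    model = IntensityGMM(
        n_components=config.gmm_components,
        tol=config.gmm_tol,
        max_iter=config.gmm_max_iter,
        random_state=config.seed,
        weighted_assign=config.weighted_assign,
    ).fit(values)
    labels = model.predict(values)
    layer, comp = select_vessel_cluster(model.fit_result_, labels, config.vessel_rule)
    i_gmm = np.zeros(green.shape, dtype=bool)
    i_gmm[sel] = layer
    log.info(
        "GMM: %d iters, means=%s, vessel component %d",
        model.n_iter_, np.round(model.means_, 4), comp,
    )
    t0 = _stage("gmm", t0)

    i_c = gray_vote(
        i_gv,
        GrayVoteParams(m=config.grayvote_m, k=config.k_complement, l_mode="max_max"),
        fov=fov_used,
    )
    # vessels carry negative vote mass in the complement pass
    i_com = binarize(-i_c, method=config.binarize_method, fov=fov_used)
    t0 = _stage("complement", t0)

    i_c_gmm = complement_vessels(i_gmm, i_com, config.post)
    n_added = int(i_c_gmm.sum() - i_gmm.sum())
    i_final = eliminate_fragments(i_c_gmm, config.elimination)
    n_removed = int(i_c_gmm.sum() - i_final.sum())
    log.info("complementation added %d px; elimination removed %d px",
             n_added, n_removed)
    t0 = _stage("postprocess", t0)

    result = {
        "I_green": green,
        "I_Gabor": i_gabor,
        "I_vessel": i_vessel,
        "I_gv": i_gv,
        "I_GMM": i_gmm,
        "I_c": i_c,
        "I_com": i_com,
        "I_C_GMM": i_c_gmm,
        "I_FINAL": i_final,
        "fov": sel,
        "manifest": {
            "source": source,
            "config_digest": config.digest(),
            "seed": config.seed,
            "gmm_means": model.means_.tolist(),
            "gmm_weights": model.weights_.tolist(),
            "vessel_component": comp,
            "pixels_added": n_added,
            "pixels_removed": n_removed,
        },
    }
    if save_dir is not None:
        _save_intermediates(result, save_dir, config)
    return result


def _save_intermediates(result: dict, save_dir, config: PipelineConfig) -> None:
    save_dir = Path(save_dir)
    save_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in result.items():
        if name == "manifest":
            continue
        if arr.dtype == bool:
            io_formats.write_mask(arr, save_dir / f"{name}.png")
        else:
            io_formats.write_gray(arr, save_dir / f"{name}.tif")
    with open(save_dir / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2)
    config.to_yaml(save_dir / "config.yaml")


def evaluate_result(result: dict, gold: np.ndarray) -> dict:
    """Convenience: metrics of I_FINAL against a gold mask, in-FOV."""
    c = confusion(result["I_FINAL"], gold, result["fov"])
    m = metrics(c)
    return {"confusion": asdict(c), "metrics": asdict(m)}
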