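"""Iterative self-supervised refinement.

Each iteration: (1) build rotation/wedge training pairs from the current
corrected cubes, (2) optionally add backprojected noise to the inputs at the
scheduled level, (3) train the network, (4) predict on the ORIGINAL cubes and
merge the predicted wedge content back into them in Fourier space.

Prediction always runs on the original extracted cubes, never on a previous
prediction, and the merge replaces only the unmeasured wedge region — the
measured Fourier content of the data is bit-for-bit carried through every
iteration, which is what prevents error accumulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import noise as noise_mod
from . import sampling
from .geometry import WedgeSpec, fourier_merge
from .network import TrainConfig, UNetConfig, build_model
from .network import train as train_network
from .nn import UNet3D
from .noise import NoiseConfig, ScheduleConfig
from .sampling import SubTomogramSet

__all__ = ["RefineConfig", "RefineState", "refine_iteration", "refine"]


@dataclass
class RefineConfig:
    crop_size: int | None = None        # default: cube size (no trimming)
    wedge: WedgeSpec = field(default_factory=WedgeSpec)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    noise_enabled: bool = True
    master_seed: int = 0
    keep_last: int = 2                  # checkpoints retained on disk


@dataclass
class RefineState:
    iteration: int
    original: np.ndarray                # (n, c, c, c), immutable reference data
    corrected: np.ndarray               # same shape, wedge progressively filled
    model: UNet3D
    config: RefineConfig
    denoise_level: float = 0.0
    loss_history: list = field(default_factory=list)
    mse_vs_previous: list = field(default_factory=list)


def _iter_seed(master: int, iteration: int, stream: int) -> int:
    """Independent per-iteration, per-purpose RNG streams below 2**31."""
    return int((master * 1_000_003 + iteration * 7919 + stream) % (2 ** 31 - 1))


def refine_iteration(state: RefineState, progress: bool = False) -> RefineState:
    """Advance the refinement by one iteration (returns an updated state)."""
    cfg = state.config
    it = state.iteration + 1
    crop = cfg.crop_size or state.original.shape[1]

    pairs = sampling.build_epoch_dataset(
        state.corrected, cfg.wedge, crop, _iter_seed(cfg.master_seed, it, 0))

    level = noise_mod.denoise_schedule(it, cfg.schedule) if cfg.noise_enabled else 0.0
    if level > 0:
        base = _iter_seed(cfg.master_seed, it, 1)
        for j, p in enumerate(pairs):
            nvol = noise_mod.backproject_noise(crop, cfg.noise, base + j)
            p.input = noise_mod.add_noise(p.input, nvol, level)

    tcfg = replace(cfg.train, rng_seed=_iter_seed(cfg.master_seed, it, 2))
    _, losses = train_network(state.model, pairs, tcfg)

    predicted = state.model.predict(state.original, batch_size=cfg.train.batch_size)
    corrected = np.stack([
        fourier_merge(orig, pred, cfg.wedge)
        for orig, pred in zip(state.original, predicted)
    ]).astype(np.float32)
    mse_prev = float(np.mean((corrected - state.corrected) ** 2))

    return RefineState(
        iteration=it,
        original=state.original,
        corrected=corrected,
        model=state.model,
        config=cfg,
        denoise_level=level,
        loss_history=state.loss_history + [losses],
        mse_vs_previous=state.mse_vs_previous + [mse_prev],
    )


def _save_state(state: RefineState, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"iter{state.iteration:02d}"
    state.model.save(outdir / f"model_{tag}.npz")
    np.savez(outdir / f"corrected_{tag}.npz", corrected=state.corrected)
    (outdir / f"state_{tag}.json").write_text(json.dumps({
        "iteration": state.iteration,
        "denoise_level": state.denoise_level,
        "loss_history": state.loss_history,
        "mse_vs_previous": state.mse_vs_previous,
    }))
    # disk economy: drop checkpoints older than keep_last iterations
    keep = state.config.keep_last
    for f in outdir.glob("*_iter*.npz"):
        n = int(f.stem.split("iter")[1])
        if n <= state.iteration - keep:
            f.unlink()
    for f in outdir.glob("state_iter*.json"):
        n = int(f.stem.split("iter")[1])
        if n <= state.iteration - keep:
            f.unlink()


def load_state(outdir, original: np.ndarray, config: RefineConfig) -> RefineState:
    """Resume from the newest checkpoint in `outdir`."""
    outdir = Path(outdir)
    metas = sorted(outdir.glob("state_iter*.json"))
    if not metas:
        raise FileNotFoundError(f"no checkpoints in {outdir}")
    meta = json.loads(metas[-1].read_text())
    it = meta["iteration"]
    tag = f"iter{it:02d}"
    model = UNet3D.load(outdir / f"model_{tag}.npz")
    with np.load(outdir / f"corrected_{tag}.npz") as z:
        corrected = z["corrected"]
    if corrected.shape != original.shape:
        raise ValueError("resume state incompatible with the supplied cubes")
    return RefineState(it, original, corrected, model, config,
                       meta["denoise_level"], meta["loss_history"],
                       meta["mse_vs_previous"])


def refine(cubes: SubTomogramSet | np.ndarray, iterations: int,
           config: RefineConfig | None = None, output_dir=None,
           continue_from=None, pretrained_model=None) -> RefineState:
    """Run the full iterative refinement.

    `continue_from` resumes from a checkpoint directory; `pretrained_model`
    warm-starts the weights from a saved model file.
    """
    config = config or RefineConfig()
    arr = cubes.cubes if isinstance(cubes, SubTomogramSet) else np.asarray(cubes)
    arr = arr.astype(np.float32)
    if len(arr) == 0:
        raise ValueError("no subtomograms supplied")

    if continue_from is not None:
        state = load_state(continue_from, arr, config)
    else:
        ucfg = replace(config.unet, rng_seed=_iter_seed(config.master_seed, 0, 3))
        model = build_model(ucfg)
        if pretrained_model is not None:
            model = UNet3D.load(pretrained_model)
        state = RefineState(0, arr, arr.copy(), model, config)

    for _ in range(iterations - state.iteration):
        state = refine_iteration(state)
        if output_dir is not None:
            _save_state(state, Path(output_dir))
    return state
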