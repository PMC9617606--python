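"""High-level modelling interface: MissingWedgeModel -> fit() -> RefineResults.

The model owns the data (extracted subtomograms) and the configuration; the
results object carries the fitted network(s), the corrected subtomograms,
the training diagnostics, and the downstream operations (whole-tomogram
prediction, gold-standard FSC between halves, recovery scoring against a
known ground truth, plotting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import synthetic, validation
from .geometry import WedgeSpec
from .network import TrainConfig, UNetConfig
from .noise import NoiseConfig, ScheduleConfig
from .predict import predict_full
from .refine import RefineConfig, RefineState, refine
from .sampling import SubTomogramSet, extract
from .tomio import Tomogram

__all__ = ["MissingWedgeModel", "RefineResults"]


class MissingWedgeModel:
    """Self-supervised missing-wedge restoration fitted to subtomograms.

    Parameters
    ----------
    subtomograms : SubTomogramSet or (n, c, c, c) array
        Extracted, contrast-inverted, normalized cubes.
    wedge : WedgeSpec
        Tilt range that defines the unsampled Fourier region.
    Remaining configs control the network, training, and the optional
    noisier-input denoising schedule.
    """

    def __init__(self, subtomograms, wedge: WedgeSpec = WedgeSpec(),
                 unet: UNetConfig | None = None,
                 train: TrainConfig | None = None,
                 noise: NoiseConfig | None = None,
                 schedule: ScheduleConfig | None = None,
                 crop_size: int | None = None,
                 denoise: bool = True):
        if isinstance(subtomograms, SubTomogramSet):
            self.subtomograms = subtomograms
            self.cubes = subtomograms.cubes
        else:
            self.cubes = np.asarray(subtomograms, dtype=np.float32)
            self.subtomograms = None
        self.config = RefineConfig(
            crop_size=crop_size,
            wedge=wedge,
            unet=unet or UNetConfig(),
            train=train or TrainConfig(),
            noise=noise or NoiseConfig(),
            schedule=schedule or ScheduleConfig(),
            noise_enabled=denoise,
        )

    @classmethod
    def from_tomogram(cls, tomo: Tomogram, mask=None, count: int = 300,
                      cube_size: int = 96, rng_seed: int = 0,
                      split: bool = False, **kwargs) -> "MissingWedgeModel":
        """Extract subtomograms from a tomogram and build the model."""
        subs = extract(tomo, mask, count, cube_size, rng_seed, split=split)
        return cls(subs, **kwargs)

    def fit(self, iterations: int = 10, seed: int = 0, output_dir=None,
            ground_truth=None, split: bool = False) -> "RefineResults":
        """Run the iterative refinement and return the results.

        With ``split=True`` (requires a SubTomogramSet extracted with
        split) the two halves are refined independently, yielding two
        networks for gold-standard validation.
        """
        cfg = replace(self.config, master_seed=seed)
        if split:
            if self.subtomograms is None or self.subtomograms.half_id is None:
                raise ValueError("split fitting requires half-assigned subtomograms")
            states = []
            for h in (0, 1):
                sub = self.subtomograms.half(h)
                out = None if output_dir is None else f"{output_dir}/half{h}"
                states.append(refine(sub, iterations,
                                     replace(cfg, master_seed=seed + h), out))
            return RefineResults(self, states[0], half_states=tuple(states),
                                 ground_truth=ground_truth)
        state = refine(self.cubes, iterations, cfg, output_dir)
        return RefineResults(self, state, ground_truth=ground_truth)


@dataclass
class RefineResults:
    """Fitted refinement: corrected cubes, network(s), and diagnostics."""

    model: MissingWedgeModel
    state: RefineState
    half_states: tuple | None = None
    ground_truth: np.ndarray | None = None
    recovery: list = field(init=False, default_factory=list)

    def __post_init__(self):
        if self.ground_truth is not None:
            self.recovery = [
                synthetic.recovery_score(c, t, self.state.config.wedge)
                for c, t in zip(self.corrected_cubes, self.ground_truth)
            ]

    # -- accessors ---------------------------------------------------------

    @property
    def corrected_cubes(self) -> np.ndarray:
        return self.state.corrected

    @property
    def network(self):
        return self.state.model

    @property
    def loss_history(self):
        """List (per iteration) of per-epoch mean absolute errors."""
        return self.state.loss_history

    @property
    def final_loss(self) -> float:
        return self.state.loss_history[-1][-1] if self.state.loss_history else np.nan

    # -- downstream operations ----------------------------------------------

    def predict(self, tomo: Tomogram, crop_size: int | None = None,
                margin: int | None = None) -> Tomogram:
        """Seamless overlap-tile prediction on a whole tomogram."""
        crop = crop_size or self.model.cubes.shape[1]
        return predict_full(tomo, self.network, crop, margin)

    def fsc_between_halves(self, **kwargs):
        """Gold-standard 3D FSC of the two half-refinements' corrected cubes."""
        if self.half_states is None:
            raise ValueError("fit with split=True to obtain half-maps")
        h1 = self.half_states[0].corrected.mean(axis=0)
        h2 = self.half_states[1].corrected.mean(axis=0)
        return validation.gold_standard_3dfsc(
            h1, h2, cube=min(h1.shape), n_cubes=1, **kwargs)

    def summary(self) -> str:
        """Human-readable fit report."""
        st = self.state
        lines = [
            "Missing-wedge restoration fit",
            "=" * 34,
            f"subtomograms        : {len(st.original)} cubes of "
            f"{st.original.shape[1]}^3 voxels",
            f"wedge               : [{st.config.wedge.tilt_min:g}, "
            f"{st.config.wedge.tilt_max:g}] deg (tilt axis Y)",
            f"iterations          : {st.iteration}",
            f"final denoise level : {st.denoise_level:g}",
            f"network parameters  : {st.model.n_params:,}",
        ]
        if st.loss_history:
            lines.append(f"final training MAE  : {self.final_loss:.5f}")
        if st.mse_vs_previous:
            lines.append(f"last delta-MSE      : {st.mse_vs_previous[-1]:.3e}")
        if self.recovery:
            arr = np.array(self.recovery)
            lines.append(
                "recovery vs truth   : real-space r = "
                f"{arr[:, 0].mean():.3f}, wedge-region r = {arr[:, 1].mean():.3f}, "
                f"passband r = {arr[:, 2].mean():.3f}"
            )
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training MAE per epoch, concatenated across iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        flat = [v for it in self.loss_history for v in it]
        ax.plot(range(1, len(flat) + 1), flat, marker="o", ms=3)
        for i in range(1, len(self.loss_history)):
            ax.axvline(i * len(self.loss_history[0]) + 0.5, color="0.8", lw=0.8)
        ax.set_xlabel("epoch (all iterations)")
        ax.set_ylabel("training MAE")
        return ax
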