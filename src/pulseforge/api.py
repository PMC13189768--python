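"""High-level modelling interface: build a model, fit it, inspect results.

Follows the model/results convention of the statistical-modelling ecosystem:
:class:`RPPGModel` holds the configuration and data plumbing; calling
:meth:`RPPGModel.fit` runs the optimization and returns an
:class:`RPPGResults` object carrying the trained network, the loss history,
held-out predictions and metrics, and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelConfig, RPPGNet, build_model, save_checkpoint
from .pipeline import EvalResult, TrainConfig, evaluate, train
from .pulsesignal import DEFAULT_BAND, estimate_hr

__all__ = ["RPPGModel", "RPPGResults"]


class RPPGModel:
    """A configured (untrained) pulse-estimation model bound to training data.

    Parameters
    ----------
    train_data, val_data : sequences of samples with ``.clip`` / ``.bvp``
        (e.g. :class:`pulseforge.synth.SynthSample` or fixture samples).
    config : ModelConfig, optional; inferred at desk scale from the data
        geometry when omitted.
    seed : controls parameter initialization.
    """

    def __init__(self, train_data, val_data=None, config: ModelConfig | None = None,
                 seed: int = 0):
        if not train_data:
            raise ValueError("train_data must be non-empty")
        self.train_data = list(train_data)
        self.val_data = list(val_data) if val_data else []
        if config is None:
            d = self.train_data[0].clip.d
            config = ModelConfig.desk_preset(d=d)
        self.config = config
        self.seed = seed
        self.net: RPPGNet = build_model(config, seed=seed)

    @classmethod
    def from_samples(cls, samples, val_fraction: float = 0.0, **kwargs) -> "RPPGModel":
        samples = list(samples)
        n_val = int(np.floor(val_fraction * len(samples)))
        if n_val:
            return cls(samples[:-n_val], samples[-n_val:], **kwargs)
        return cls(samples, **kwargs)

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False) -> "RPPGResults":
        tc = train_config or TrainConfig(seed=self.seed)
        self.net, history = train(self.net, self.train_data, self.val_data,
                                  tc, verbose=verbose)
        return RPPGResults(model=self, net=self.net, history=history,
                           train_config=tc)


@dataclass
class RPPGResults:
    """Fitted-model container: trained parameters, history, diagnostics."""

    model: RPPGModel
    net: RPPGNet
    history: pd.DataFrame
    train_config: TrainConfig
    _eval_cache: EvalResult | None = field(default=None, repr=False)

    def predict(self, frames) -> np.ndarray:
        """Predicted pulse wave(s) for raw clip pixel arrays."""
        return self.net.predict(frames)

    def predict_hr(self, frames, band=DEFAULT_BAND) -> np.ndarray:
        """Heart-rate readout (BPM) per clip."""
        waves = np.atleast_2d(self.net.predict(frames))
        fps = self.model.train_data[0].clip.fps
        return np.array([estimate_hr(w, fps, band) for w in waves])

    def evaluate(self, test_data, band=DEFAULT_BAND) -> EvalResult:
        res = evaluate(self.net, test_data, band=band)
        self._eval_cache = res
        return res

    def save(self, path) -> None:
        save_checkpoint(path, self.net)

    def summary(self, eval_result: EvalResult | None = None) -> str:
        res = eval_result or self._eval_cache
        lines = ["Pulse-estimation model fit", "=" * 40,
                 self.net.describe(), "-" * 40,
                 f"epochs: {len(self.history)}"]
        if len(self.history):
            lines.append(f"train loss: {self.history['train_loss'].iloc[0]:.4f} "
                         f"-> {self.history['train_loss'].iloc[-1]:.4f}")
            if "val_loss" in self.history:
                lines.append(f"val loss:   {self.history['val_loss'].iloc[-1]:.4f}")
        if res is not None:
            r = res.report
            ba = r.bland_altman
            lines += ["-" * 40,
                      f"held-out clips: {r.n}",
                      f"MAE  {r.mae:7.2f} BPM",
                      f"RMSE {r.rmse:7.2f} BPM",
                      f"MAPE {r.mape:7.2f} %",
                      f"rho  {r.rho:7.3f}",
                      f"SNR  {r.snr:7.2f} dB",
                      f"Bland-Altman bias {ba.bias:.2f} BPM, "
                      f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]"]
        return "\n".join(lines)

    def plot_bland_altman(self, eval_result: EvalResult | None = None, ax=None):
        """Agreement plot of predicted vs reference HR differences."""
        import matplotlib.pyplot as plt

        res = eval_result or self._eval_cache
        if res is None:
            raise ValueError("run evaluate() first or pass an EvalResult")
        ok = res.rows[res.rows["valid"]]
        mean_hr = (ok["pred_bpm"] + ok["ref_bpm"]) / 2.0
        diff = ok["pred_bpm"] - ok["ref_bpm"]
        ba = res.report.bland_altman
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(mean_hr, diff, s=14, alpha=0.7)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of predicted and reference HR (BPM)")
        ax.set_ylabel("prediction - reference (BPM)")
        ax.set_title("Bland-Altman agreement")
        return ax
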