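"""Plot helpers for training runs (learning curves, parameter trajectories,
dynamic-strength courses). All functions save a PNG and return the path."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiment import EpisodeRecord, records_to_frame

__all__ = ["plot_learning_curves", "plot_parameter_trajectories", "plot_strength_course"]


def plot_learning_curves(records: Sequence[EpisodeRecord], path: str | Path) -> Path:
    frame = records_to_frame(records)
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(frame["episode"], frame["reward"], lw=0.8)
    axes[0].set_ylabel("reward")
    axes[1].plot(frame["episode"], frame["distance"], lw=0.8, color="tab:red")
    axes[1].set_ylabel("D(F, G)")
    axes[2].plot(frame["episode"], frame["crosscorr"], lw=0.8, color="tab:green")
    axes[2].set_ylabel("max cross-corr")
    axes[2].set_xlabel("episode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_parameter_trajectories(
    records: Sequence[EpisodeRecord], path: str | Path, inhibitory: np.ndarray | None = None
) -> Path:
    episodes = [r.episode for r in records]
    names = ("tau_fac", "tau_rec", "U_SE")
    fig, axes = plt.subplots(len(names), 1, figsize=(7, 8), sharex=True)
    for ax, name in zip(axes, names):
        values = np.stack([r.params[name] for r in records])
        if inhibitory is not None:
            exc = values[:, ~inhibitory]
            inh = values[:, inhibitory]
            if exc.size:
                ax.plot(episodes, exc.mean(axis=1), label="excitatory")
            if inh.size:
                ax.plot(episodes, inh.mean(axis=1), label="inhibitory")
            ax.legend(frameon=False, fontsize=8)
        else:
            ax.plot(episodes, values.mean(axis=1))
        ax.set_ylabel(name)
    axes[-1].set_xlabel("episode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_strength_course(
    records: Sequence[EpisodeRecord], path: str | Path, normalize: bool = True
) -> Path:
    """Per-episode time-averaged dynamic strength <S(t)> for trained vs
    untrained synapses, optionally min-max normalized to [0, 1]."""
    episodes = [r.episode for r in records]
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, (label, S) in zip(
        axes,
        (
            ("untrained (hidden->output)", np.stack([r.mean_S_ho for r in records])),
            ("trained (input->hidden)", np.stack([r.mean_S_ih for r in records])),
        ),
    ):
        course = S.mean(axis=1)
        span = np.ptp(course)
        if normalize and span > 0:
            course = (course - course.min()) / span
        ax.plot(episodes, course, lw=0.9)
        ax.set_ylabel("<S(t)>")
        ax.set_title(label, fontsize=9)
    axes[-1].set_xlabel("episode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
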