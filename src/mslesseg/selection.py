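"""Checkpoint selection from the validation-loss history.

After training, the network used for inference is not simply the one
with the lowest validation loss: batch shuffling can produce a lucky low
loss inside an unstable stretch of the history.  Instead, a moving
window (50 epochs) slides one epoch at a time over the last 150 epochs;
every window is scored by the variance of its validation losses, and
within the most stable (minimum-variance) window the epochs are ranked
by ascending loss.  The best-ranked epoch whose checkpoint actually
exists on disk is selected; if none exists in that window, the search
proceeds to the window with the next-smallest variance.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class SelectionError(RuntimeError):
    """No saved checkpoint available anywhere in the examined span."""


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Window geometry for the variance-based selection rule."""

    window: int = 50
    span: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.window <= self.span):
            raise ValueError("require 0 < window <= span")


def select_checkpoint(history, spec: SelectionSpec = SelectionSpec()) -> int:
    """Return the epoch index (0-based) of the selected checkpoint.

    ``history`` is a :class:`~mslesseg.trainer.LossHistory`.  Ties in
    window variance break toward the later window; ties in loss within a
    window break toward the later epoch.
    """
    losses = np.asarray(history.val_loss, dtype=np.float64)
    saved = np.asarray(history.checkpoint_saved, dtype=bool)
    n = losses.size
    if n < spec.span:
        raise ValueError(
            f"history length {n} is shorter than the selection span {spec.span}"
        )
    start = n - spec.span
    seg = losses[start:]
    seg_saved = saved[start:]

    n_windows = spec.span - spec.window + 1
    variances = np.empty(n_windows)
    for i in range(n_windows):
        variances[i] = seg[i : i + spec.window].var()  # population variance

    # ascending variance; later window wins ties
    window_order = sorted(range(n_windows), key=lambda i: (variances[i], -i))
    for wi in window_order:
        w_losses = seg[wi : wi + spec.window]
        # ascending loss; later epoch wins ties
        epoch_order = sorted(
            range(spec.window), key=lambda j: (w_losses[j], -j)
        )
        for j in epoch_order:
            if seg_saved[wi + j]:
                return start + wi + j
    raise SelectionError(
        "no saved checkpoint in the last "
        f"{spec.span} epochs; fall back to the best-loss checkpoint"
    )
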