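"""Scikit-learn style estimator facade over the segmentation pipeline.

:class:`LesionSegmenter` wires slice preparation, the multi-branch
network, the training loop, checkpoint selection and tri-planar fusion
into a single ``fit``/``predict`` object that composes with sklearn
model-selection utilities.  The underlying modules remain usable on
their own for finer control.
"""

from __future__ import annotations

import tempfile

import numpy as np
from sklearn.base import BaseEstimator

from .dataprep import (
    LesionMask,
    MultiModalVolume,
    PLANES,
    normalize_intensity,
    select_training_slices,
    slice_volume,
)
from .fusion import ThresholdPolicy, predict_volume
from .losses import LossSpec
from .network import NetConfig, build_model, summarize
from .selection import SelectionSpec, select_checkpoint
from .trainer import TrainConfig, load_checkpoint, train


class LesionSegmenter(BaseEstimator):
    """Multi-branch 2D U-Net lesion segmenter with tri-planar fusion.

    Parameters follow sklearn conventions (all stored unmodified; the
    work happens in :meth:`fit`).

    Parameters
    ----------
    n0 : int
        Base filter count of the network.
    variant : str
        "full" or one of the ablation variants.
    planes : tuple of str
        Planes used for training slices and inference fusion.
    empty_stride : int
        Keep every this-many-th empty training slice.
    threshold : float
        Probability cut applied to the fused volume.
    max_epochs, patience, batch_size, initial_lr : training schedule.
    use_selection : bool
        Pick the inference checkpoint with the variance-window rule when
        the history is long enough (else fall back to the best epoch).
    random_state : int
        Seed for initialization, shuffling and augmentation.

    Attributes
    ----------
    model_ : the trained network.
    history_ : per-epoch loss trace.
    selected_epoch_ : 1-based epoch used for inference.
    summary_ : parameter counts of the built model.
    """

    def __init__(self, n0=32, variant="full", modalities=("FLAIR", "T1w", "T2w"),
                 planes=PLANES, empty_stride=30, threshold=0.5,
                 max_epochs=100, patience=200, batch_size=15,
                 initial_lr=3e-4, loss="dice_bce", use_selection=True,
                 random_state=0):
        self.n0 = n0
        self.variant = variant
        self.modalities = modalities
        self.planes = planes
        self.empty_stride = empty_stride
        self.threshold = threshold
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.loss = loss
        self.use_selection = use_selection
        self.random_state = random_state

    def _prepare(self, X, y):
        records = []
        for vol, mask in zip(X, y):
            vol = normalize_intensity(vol)
            for plane in self.planes:
                recs = slice_volume(vol, mask, plane)
                records.extend(
                    select_training_slices(recs, self.empty_stride)
                )
        return records

    def fit(self, X, y, validation_data=None):
        """Train on volumes.

        X : sequence of MultiModalVolume; y : sequence of LesionMask.
        ``validation_data`` is an optional (X_val, y_val) pair; when
        absent the training records double as the validation set (the
        desk-scale overfitting regime).
        """
        X = list(X)
        y = [m if isinstance(m, LesionMask) else LesionMask(m) for m in y]
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        records = self._prepare(X, y)
        if not records:
            raise ValueError("no training slices after selection")
        if validation_data is not None:
            val_records = self._prepare(*validation_data)
        else:
            val_records = records

        cfg = NetConfig(
            n0=self.n0,
            modalities=tuple(self.modalities),
            variant=self.variant,
            seed=self.random_state,
        )
        self.model_ = build_model(cfg)
        self.summary_ = summarize(self.model_)

        self._ckpt_dir = tempfile.mkdtemp(prefix="mslesseg_ckpt_")
        tcfg = TrainConfig(
            initial_lr=self.initial_lr,
            batch_size_train=self.batch_size,
            early_stop_patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.random_state,
            checkpoint_dir=self._ckpt_dir,
        )
        self.model_, self.history_ = train(
            self.model_, records, val_records, tcfg, LossSpec(kind=self.loss)
        )
        spec = SelectionSpec()
        if self.use_selection and len(self.history_) >= spec.span:
            epoch0 = select_checkpoint(self.history_, spec)
        else:
            epoch0 = self.history_.best_epoch
        self.selected_epoch_ = epoch0 + 1
        load_checkpoint(self.model_, self._ckpt_dir, self.selected_epoch_)
        return self

    def predict_proba(self, X):
        """Fused tri-planar probability volume for each input volume."""
        self._check_fitted()
        out = []
        for vol in X:
            vol = normalize_intensity(vol)
            fused, _ = predict_volume(
                self.model_, vol, ThresholdPolicy(value=self.threshold)
            )
            out.append(fused)
        return out

    def predict(self, X):
        """Binary lesion mask for each input volume."""
        self._check_fitted()
        out = []
        for vol in X:
            vol = normalize_intensity(vol)
            _, mask = predict_volume(
                self.model_, vol, ThresholdPolicy(value=self.threshold)
            )
            out.append(mask)
        return out

    def score(self, X, y):
        """Mean volume DSC over (X, y) pairs."""
        from .metrics import voxel_metrics

        preds = self.predict(X)
        ds = []
        for pred, gt in zip(preds, y):
            gt = gt if isinstance(gt, LesionMask) else LesionMask(gt)
            d = voxel_metrics(pred.data, gt.data)[0]
            if not np.isnan(d):
                ds.append(d)
        return float(np.mean(ds)) if ds else float("nan")

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("LesionSegmenter is not fitted")
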