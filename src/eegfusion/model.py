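"""Model/Results front end for the hybrid seizure classifier.

``SeizureClassifier`` bundles labeled data with the architecture, transform
and training configuration; ``fit()`` performs the end-to-end optimization
and returns a ``SeizureClassifierResults`` carrying the trained network, the
training trace and prediction/summary methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import InvalidInputError
from .architecture import (
    METHOD_BRANCHES,
    ArchConfig,
    HybridNetwork,
    count_parameters,
    stack_hybrids,
)
from .evaluation import accuracy, evaluate_in_batches
from .segment import EEGSegment, labels_to_indices
from .training import TrainConfig, TrainRecord, train_model
from .transforms import HybridInput, TransformConfig, make_hybrid

__all__ = ["SeizureClassifier", "SeizureClassifierResults"]


class SeizureClassifier:
    """A hybrid (or single-input) CNN seizure classifier bound to data.

    Parameters
    ----------
    hybrids
        Labeled ``HybridInput`` samples (all sharing one transform config).
    method
        ``"Hybrid"`` (all four branches) or one of the single-input
        baselines ``"EEG"``, ``"FFT"``, ``"STFT"``, ``"DWT"``.
    arch, train_config
        Architecture and optimization settings; defaults follow the study
        configuration.

    Examples
    --------
    >>> from eegfusion import SeizureClassifier, SynthConfig, generate_dataset
    >>> segs = generate_dataset(SynthConfig(n_per_class=5, length=512))
    >>> res = SeizureClassifier.from_segments(segs).fit(seed=0, max_epochs=2)
    >>> res.predict(res.model_data.hybrids).shape
    (10,)
    """

    def __init__(
        self,
        hybrids: list[HybridInput],
        method: str = "Hybrid",
        arch: ArchConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        if method not in METHOD_BRANCHES:
            raise InvalidInputError(
                f"method must be one of {sorted(METHOD_BRANCHES)}"
            )
        if not hybrids:
            raise InvalidInputError("no training samples provided")
        self.hybrids = list(hybrids)
        self.labels = labels_to_indices([h.raw for h in self.hybrids])
        self.method = method
        self.branches = METHOD_BRANCHES[method]
        self.arch = arch or ArchConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_segments(
        cls,
        segments: list[EEGSegment],
        method: str = "Hybrid",
        transform_config: TransformConfig | None = None,
        **kwargs,
    ) -> "SeizureClassifier":
        """Build the classifier directly from raw segments."""
        hybrids = [make_hybrid(s, transform_config) for s in segments]
        return cls(hybrids, method=method, **kwargs)

    def fit(self, seed: int | None = None, **overrides) -> "SeizureClassifierResults":
        """Train the network; returns a results object.

        ``overrides`` replace individual ``TrainConfig`` fields for this fit
        (e.g. ``max_epochs=30``).
        """
        import dataclasses

        cfg = self.train_config
        if seed is not None:
            overrides["seed"] = int(seed)
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        record = train_model(
            self.hybrids, self.labels, cfg, branches=self.branches, arch=self.arch
        )
        return SeizureClassifierResults(self, record)


class SeizureClassifierResults:
    """Fitted-model container: trained network, training trace, diagnostics."""

    def __init__(self, model_data: SeizureClassifier, record: TrainRecord) -> None:
        self.model_data = model_data
        self.record = record
        self.network: HybridNetwork = record.model

    # -- predictions -------------------------------------------------------
    def _arrays(self, hybrids: list[HybridInput]) -> dict[str, np.ndarray]:
        return stack_hybrids(hybrids, self.network.branch_names)

    def predict_proba(self, hybrids: list[HybridInput]) -> np.ndarray:
        """Per-sample class probabilities (normal, epileptic)."""
        arrays = self._arrays(hybrids)
        probs = []
        idx = np.arange(len(hybrids))
        for start in range(0, idx.size, 8):
            sel = idx[start : start + 8]
            xb = {k: np.ascontiguousarray(a[:, sel]) for k, a in arrays.items()}
            probs.append(self.network.predict_proba(xb))
        return np.vstack(probs)

    def predict(self, hybrids: list[HybridInput]) -> np.ndarray:
        arrays = self._arrays(hybrids)
        return evaluate_in_batches(self.network, arrays, np.arange(len(hybrids)))

    def accuracy(self, hybrids: list[HybridInput] | None = None) -> float:
        """Accuracy on the given samples (training set by default)."""
        hybrids = hybrids if hybrids is not None else self.model_data.hybrids
        y = labels_to_indices([h.raw for h in hybrids])
        return accuracy(self.predict(hybrids), y)

    # -- diagnostics -------------------------------------------------------
    @property
    def final_loss(self) -> float:
        return self.record.losses[-1]

    def parameter_counts(self) -> dict:
        return count_parameters(self.network)

    def summary(self) -> str:
        """Human-readable fit summary."""
        counts = self.parameter_counts()
        cfg = self.record.config
        lines = [
            "Hybrid seizure classifier fit",
            "=" * 46,
            f"method:            {self.model_data.method}",
            f"branches:          {', '.join(self.network.branch_names)}",
            f"fused feature dim: {self.network.fused_dim}",
            f"parameters:        {counts['total']}",
        ]
        for name, n in counts["breakdown"].items():
            lines.append(f"  {name:<16} {n}")
        lines += [
            f"samples:           {len(self.model_data.hybrids)}",
            f"epochs:            {len(self.record.losses)} "
            f"(batch {cfg.batch_size}, lr0 {cfg.initial_lr}, "
            f"halved every {cfg.lr_halving_period_epochs})",
            f"l2 lambda:         {cfg.l2_lambda}",
            f"final loss:        {self.final_loss:.4f}",
            f"final train acc:   {self.record.accuracies[-1]:.4f}",
        ]
        if self.record.clip_events:
            lines.append(f"log-prob clips:    {self.record.clip_events}")
        return "\n".join(lines)

    def loss_trace(self) -> pd.DataFrame:
        """Per-epoch loss / accuracy / learning-rate table."""
        return pd.DataFrame(
            {
                "loss": self.record.losses,
                "train_accuracy": self.record.accuracies,
                "learning_rate": self.record.learning_rates,
            }
        )

    def plot_loss(self, ax=None):
        """Plot the training loss trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.record.losses, label="loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("regularized cross-entropy")
        ax.legend()
        return ax
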