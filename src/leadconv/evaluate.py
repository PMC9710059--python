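"""Evaluation and reporting for lead conversion.

Metrics are computed per segment and then aggregated: Pearson r is
averaged and median-ed across segments (signed — negative averages are
meaningful), RMSE and SSIM are averaged.  Segments on which r is undefined
(a constant converted or measured signal) are excluded from the r
aggregation but kept for RMSE/SSIM; the per-lead count of segments that
entered the r aggregation is reported so exclusions are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    SSIM_DATA_RANGE, SSIM_K1, SSIM_K2, SSIM_WINDOW,
    ConstantSignalError, pearson_r, rmse, ssim_1d,
)
from .models import ConversionModel, ModelConfig
from .preprocess import SegmentDataset
from .train import TrainConfig, fit
from .models import build_model

__all__ = [
    "EvalReport", "evaluate_conversion", "interlead_correlation_table",
    "compare_architectures", "plot_conversion_example",
]

REPORT_COLUMNS = ["lead", "r_avg", "r_med", "rmse_avg", "ssim_avg",
                  "n_segments", "n_r_used", "group"]


@dataclass
class EvalReport:
    """Per-target-lead metric table for one evaluation group."""

    table: pd.DataFrame
    group: str = "all"
    ssim_params: dict = field(default_factory=lambda: {
        "window_length": SSIM_WINDOW, "data_range": SSIM_DATA_RANGE,
        "k1": SSIM_K1, "k2": SSIM_K2})

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        hdr = (f"group: {self.group}   "
               f"ssim(window={self.ssim_params['window_length']}, "
               f"data_range={self.ssim_params['data_range']}, "
               f"k1={self.ssim_params['k1']}, k2={self.ssim_params['k2']})")
        return hdr + "\n" + self.table.to_string(
            index=False, float_format=lambda v: f"{v:.3f}")


def _metric_rows(preds: dict[str, np.ndarray], dataset: SegmentDataset,
                 leads, idx, group: str, ssim_kwargs: dict) -> pd.DataFrame:
    rows = []
    for lead in leads:
        y_true = dataset.X[lead][idx]
        y_pred = preds[lead][idx]
        rs, rmses, ssims = [], [], []
        for yt, yp in zip(y_true, y_pred):
            try:
                rs.append(pearson_r(yp, yt))
            except ConstantSignalError:
                pass
            rmses.append(rmse(yp, yt))
            ssims.append(ssim_1d(yp, yt, **ssim_kwargs))
        rows.append({
            "lead": lead,
            "r_avg": float(np.mean(rs)) if rs else np.nan,
            "r_med": float(np.median(rs)) if rs else np.nan,
            "rmse_avg": float(np.mean(rmses)),
            "ssim_avg": float(np.mean(ssims)),
            "n_segments": int(len(y_true)),
            "n_r_used": int(len(rs)),
            "group": group,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def evaluate_conversion(
    model: ConversionModel,
    dataset: SegmentDataset,
    group_by_label: bool = False,
    ssim_kwargs: dict | None = None,
    batch_size: int = 64,
) -> list[EvalReport]:
    """Evaluate a conversion model on a preprocessed dataset.

    Returns one report over all segments, or one per diagnostic label class
    when ``group_by_label`` is set (segments without labels form the
    ``"(unlabelled)"`` group; empty groups are skipped).
    """
    ssim_kwargs = ssim_kwargs or {}
    x = dataset.X[model.config.reference_lead]
    preds = model.predict(x, batch_size=batch_size)
    leads = model.config.target_leads
    if not group_by_label:
        idx = np.arange(len(dataset))
        return [EvalReport(_metric_rows(preds, dataset, leads, idx, "all",
                                        ssim_kwargs))]
    groups: dict[str, list[int]] = {}
    for i, labels in enumerate(dataset.labels):
        if labels:
            for tag in sorted(labels):
                groups.setdefault(tag, []).append(i)
        else:
            groups.setdefault("(unlabelled)", []).append(i)
    reports = []
    for tag in sorted(groups):
        idx = np.asarray(groups[tag])
        reports.append(EvalReport(
            _metric_rows(preds, dataset, leads, idx, tag, ssim_kwargs),
            group=tag))
    return reports


def interlead_correlation_table(
    dataset: SegmentDataset, reference_lead: str = "II"
) -> pd.Series:
    """Mean Pearson correlation between the reference lead's segments and
    every other lead's aligned segments (constant segments excluded)."""
    ref = dataset.X[reference_lead]
    out = {}
    for lead in dataset.leads:
        if lead == reference_lead:
            continue
        vals = []
        for a, b in zip(ref, dataset.X[lead]):
            try:
                vals.append(pearson_r(a, b))
            except ConstantSignalError:
                continue
        out[lead] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name=f"r_vs_{reference_lead}")


def compare_architectures(
    train_set: SegmentDataset,
    val_set: SegmentDataset,
    test_set: SegmentDataset,
    families: tuple[str, ...],
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """One-to-one architecture comparison: train each family with identical
    seeds/configuration and report held-out average/median r."""
    from dataclasses import replace

    if len(model_config.target_leads) != 1:
        raise ValueError("architecture comparison is a one-to-one protocol")
    rows = []
    for family in families:
        cfg = replace(model_config, family=family)
        model = build_model(cfg, seed=train_config.seed)
        model, hist = fit(model, train_set, val_set, train_config)
        report = evaluate_conversion(model, test_set)[0].table
        rows.append({
            "family": family,
            "r_avg": report["r_avg"].iloc[0],
            "r_med": report["r_med"].iloc[0],
            "epochs": hist.n_epochs,
        })
    return pd.DataFrame(rows)


def plot_conversion_example(
    model: ConversionModel,
    dataset: SegmentDataset,
    segment_index: int = 0,
    path: str | Path | None = None,
):
    """Measured-vs-converted overlay, one row per target lead."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = dataset.X[model.config.reference_lead][segment_index:segment_index + 1]
    preds, _ = model.forward(x, train=False)
    leads = model.config.target_leads
    t = np.arange(x.shape[1]) / dataset.fs
    fig, axes = plt.subplots(len(leads), 1, figsize=(8, 1.4 * len(leads)),
                             sharex=True, squeeze=False)
    for ax, lead in zip(axes[:, 0], leads):
        ax.plot(t, dataset.X[lead][segment_index], lw=0.8, label="measured")
        ax.plot(t, preds[lead][0], lw=0.8, label="converted")
        ax.set_ylabel(lead)
        ax.set_ylim(-1.1, 1.1)
    axes[0, 0].legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("time [s]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
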