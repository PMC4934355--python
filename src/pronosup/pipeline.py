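"""End-to-end convenience chain: raw recording → orientation → phases →
features.  Thin composition of the per-stage modules, used by the CLI, the
examples and the evaluation scripts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureVector, compute_features
from .orientation import FusionConfig, OrientationTrace, estimate_orientation, lowpass
from .segmentation import PhaseSegmentation, SegmentationConfig, segment_phases
from .signal_io import Recording

__all__ = ["ProcessedRecording", "process_recording", "corpus_feature_table"]


@dataclass
class ProcessedRecording:
    orientation: OrientationTrace
    segmentation: PhaseSegmentation
    features: FeatureVector
    gyro_x_filtered: np.ndarray


def process_recording(rec: Recording,
                      fusion: FusionConfig | None = None,
                      seg_cfg: SegmentationConfig | None = None) -> ProcessedRecording:
    """Run the full chain on the performing-side wrist trace."""
    fusion = fusion or FusionConfig()
    trace = rec.wrist_trace()
    filtered = lowpass(trace, fusion)
    otrace = estimate_orientation(filtered, fusion, prefilter=False)
    gyro_x = filtered.gyro[:, 0]
    seg = segment_phases(otrace, gyro_x, seg_cfg)
    s, e = seg["PS"]
    fv = compute_features(gyro_x[s:e], trace.t[s:e])
    return ProcessedRecording(orientation=otrace, segmentation=seg,
                              features=fv, gyro_x_filtered=gyro_x)


def corpus_feature_table(recordings, labels: pd.DataFrame,
                         fusion: FusionConfig | None = None,
                         seg_cfg: SegmentationConfig | None = None) -> pd.DataFrame:
    """Feature table (one row per recording, id + features + label) for a
    generated corpus; recordings that fail segmentation are skipped with a
    note in the ``error`` column."""
    rows = []
    for rec, (_, meta) in zip(recordings, labels.iterrows()):
        row = {"recording_id": meta["recording_id"], "label": int(meta["label"])}
        try:
            proc = process_recording(rec.recording, fusion, seg_cfg)
            row.update(proc.features.as_dict())
        except Exception as exc:  # keep corpus runs going; caller inspects
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
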