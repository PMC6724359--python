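"""End-to-end streaming monitor: ECG + IMU in, vitals + annotations + alerts out.

Replays time-aligned ECG and IMU sources through the full pipeline the way
the wearable's companion app consumes them: per 8 s ECG window it detects
beats, updates HR (and RR once 30 s of history exists), scores the window
with the annotation model, classifies concurrent IMU windows, and emits one
:class:`MonitorEvent`.  Alerts are debounced: one ``abnormal_beat`` alert per
contiguous run of abnormal windows, one ``fall`` alert per contiguous run of
fall windows.  Replaying the same inputs with the same checkpoints yields
byte-identical logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation_net import ABNORMAL_BEAT_CLASSES, annotate
from .signal_io import EcgRecord, ImuRecord
from .vitals import detect_qrs, estimate_hr, estimate_rr

__all__ = ["MonitorEvent", "run_monitor", "events_to_jsonl"]


@dataclass
class MonitorEvent:
    t: float                               # window end, s
    hr: float | None
    rr: float | None
    beats: list[dict] = field(default_factory=list)
    activity: str | None = None
    alerts: list[str] = field(default_factory=list)
    gap: bool = False

    def to_json(self) -> str:
        def r(x):
            return None if x is None or (isinstance(x, float) and np.isnan(x)) \
                else round(float(x), 3)
        return json.dumps({
            "t": r(self.t), "hr": r(self.hr), "rr": r(self.rr),
            "beats": self.beats, "activity": self.activity,
            "alerts": sorted(self.alerts), "gap": self.gap,
        }, sort_keys=True)


def run_monitor(ecg: EcgRecord, imu: ImuRecord | None = None,
                annotation_model=None, activity_model=None,
                win_s: float = 8.0, out_path=None) -> list[MonitorEvent]:
    """Run the monitoring loop over a recorded (replayed) session.

    Sources must share t = 0.  Returns the event list; when ``out_path`` is
    given the events are also written as JSON lines.
    """
    fs = ecg.fs
    L = int(round(win_s * fs))
    n_win = len(ecg.samples) // L
    try:
        all_beats = detect_qrs(ecg)
    except ValueError:
        all_beats = []
    hr_series = estimate_hr(all_beats) if len(all_beats) >= 3 else None
    rr_series = None
    if ecg.duration_s >= 30 and len(all_beats) >= 20:
        rr_series = estimate_rr(ecg, all_beats)

    ann = None
    if annotation_model is not None and all_beats:
        ann = annotate(annotation_model, ecg, all_beats)
    act_windows = []
    if activity_model is not None and imu is not None:
        from .activity_net import classify_stream
        act_windows = classify_stream(activity_model, imu)

    events: list[MonitorEvent] = []
    prev_abnormal = False
    prev_fall = False
    for w in range(n_win):
        t0, t1 = w * win_s, (w + 1) * win_s
        ev = MonitorEvent(t=t1, hr=None, rr=None)
        if hr_series is not None:
            m = (hr_series.t >= t0) & (hr_series.t < t1)
            if m.any():
                ev.hr = float(np.mean(hr_series.hr[m]))
        if rr_series is not None:
            m = (rr_series.t <= t1) & ~np.isnan(rr_series.rr)
            if m.any():
                ev.rr = float(rr_series.rr[m][-1])
        window_abnormal = False
        if ann is not None:
            for b, cls, conf in ann.beat_annotations:
                if t0 <= b.time_s < t1:
                    ev.beats.append({"index": int(b.index), "class": cls,
                                     "confidence": round(conf, 3)})
                    if cls in ABNORMAL_BEAT_CLASSES:
                        window_abnormal = True
        window_fall = False
        in_win = [(t, c, p) for t, c, p in act_windows if t0 <= t < t1]
        if in_win:
            names = [c for _, c, _ in in_win]
            if "fall" in names:
                ev.activity = "fall"
                window_fall = True
            else:
                ev.activity = max(set(names), key=names.count)
        if window_abnormal and not prev_abnormal:
            ev.alerts.append("abnormal_beat")
        if window_fall and not prev_fall:
            ev.alerts.append("fall")
        prev_abnormal = window_abnormal
        prev_fall = window_fall
        if len(all_beats) == 0:
            ev.gap = True
        events.append(ev)
    if out_path is not None:
        events_to_jsonl(events, out_path)
    return events


def events_to_jsonl(events: list[MonitorEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")
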