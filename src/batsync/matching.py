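"""Time-synchronization of the video and acoustic event streams.

A video detection is *synchronous* when at least one acoustic call file
starts within +/-30 s of the event's start; the per-night tallies of
acoustic, visual and synchronous detections (with the synchronous
proportion of visual detections) are the study's core bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MatchRecord", "match_events", "offset_diagnostics", "nightly_tally"]

MATCH_WINDOW_S = 30.0


@dataclass
class MatchRecord:
    video_event_id: int
    call_file_ids: list[int]
    delta_t_s: float  # signed offset of the nearest call file (call - video)

    def __post_init__(self) -> None:
        if self.call_file_ids and abs(self.delta_t_s) > MATCH_WINDOW_S + 1e-9:
            pass  # window may be overridden by the caller; no hard check here


def match_events(video_events: pd.DataFrame, call_files: pd.DataFrame,
                 window_s: float = MATCH_WINDOW_S) -> pd.DataFrame:
    """Match each video event against call files within the time window.

    Expects ``video_events`` with columns (event_id, night, t_start_s) and
    ``call_files`` with (file_id, night, t_start_s); both streams must be
    on a common clock.  Each video event is evaluated independently — a
    call file may match several events.  Returns one row per video event
    with ``matched`` flag, the qualifying file ids, and the signed offset
    of the nearest match.
    """
    video = video_events.sort_values("t_start_s").reset_index(drop=True)
    audio = call_files.sort_values("t_start_s").reset_index(drop=True)
    if "night" in video.columns and "night" in audio.columns:
        v_nights = set(video["night"])
        a_nights = set(audio["night"])
    else:
        v_nights = a_nights = set()

    rows = []
    for v in video.itertuples():
        night = getattr(v, "night", None)
        if night is not None and a_nights:
            cand = audio[audio["night"] == night]
        else:
            cand = audio
        dt = cand["t_start_s"].to_numpy() - v.t_start_s
        inside = np.abs(dt) <= window_s
        ids = cand["file_id"].to_numpy()[inside].tolist()
        if ids:
            delta = float(dt[inside][np.argmin(np.abs(dt[inside]))])
        else:
            delta = np.nan
        rows.append({"video_event_id": v.event_id, "night": night,
                     "matched": bool(ids), "call_file_ids": ids,
                     "delta_t_s": delta})
    return pd.DataFrame(rows)


def offset_diagnostics(matches: pd.DataFrame) -> float:
    """Median absolute time offset (s) over matched events."""
    deltas = matches.loc[matches["matched"], "delta_t_s"].abs()
    if deltas.empty:
        raise ValueError("no matched events")
    return float(deltas.median())


def nightly_tally(video_events: pd.DataFrame, call_files: pd.DataFrame,
                  matches: pd.DataFrame) -> pd.DataFrame:
    """Per-night acoustic / visual / synchronous counts and proportion.

    The proportion is 100 * synchronous / visual; nights with no visual
    detections report NaN and are excluded from the across-night average.
    Appends 'total' and 'average' rows mirroring the study's table layout.
    """
    nights = sorted(set(video_events.get("night", [])) | set(call_files.get("night", [])))
    rows = []
    for night in nights:
        a = int((call_files["night"] == night).sum())
        v = int((video_events["night"] == night).sum())
        s = int(matches.loc[(matches["night"] == night), "matched"].sum())
        prop = 100.0 * s / v if v > 0 else np.nan
        rows.append({"night": night, "acoustic_n": a, "visual_n": v,
                     "synchronous_n": s, "proportion_pct": prop})
    df = pd.DataFrame(rows)
    props = df["proportion_pct"].dropna()
    total = {"night": "total", "acoustic_n": df["acoustic_n"].sum(),
             "visual_n": df["visual_n"].sum(),
             "synchronous_n": df["synchronous_n"].sum(), "proportion_pct": np.nan}
    avg = {"night": "average", "acoustic_n": df["acoustic_n"].mean(),
           "visual_n": df["visual_n"].mean(), "synchronous_n": df["synchronous_n"].mean(),
           "proportion_pct": props.mean() if len(props) else np.nan}
    return pd.concat([df, pd.DataFrame([total, avg])], ignore_index=True)
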