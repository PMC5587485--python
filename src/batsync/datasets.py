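"""Published per-night and per-event counts from the field study.

The original 20-night field campaign (thermal video + ultrasonic
detectors over a Hawaiian macadamia orchard, autumn 2014) deposited no raw
recordings, but its printed tallies are complete: per-night acoustic /
visual / synchronous counts, visual detections cross-classified by
proximity and flight type with/without associated acoustics, the same for
the multi-bat subset by interaction, and the summary of search-phase call
metrics.  These loaders reproduce those tables so the statistics layer can
be exercised against the published numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "nightly_counts", "proximity_flight_counts", "interaction_counts",
    "call_metric_summary", "events_from_counts",
]

_NIGHTLY = [
    # (date, acoustic, visual, synchronous)
    ("09/08", 19, 24, 12), ("09/09", 24, 43, 13), ("09/10", 324, 20, 13),
    ("09/11", 291, 7, 4), ("09/12", 79, 3, 2), ("09/15", 36, 19, 3),
    ("09/16", 229, 47, 21), ("09/17", 330, 27, 9), ("09/18", 2, 56, 0),
    ("09/19", 7, 24, 1), ("09/22", 7, 13, 1), ("09/23", 3, 17, 1),
    ("09/24", 3, 22, 0), ("09/25", 1, 20, 0), ("10/06", 30, 15, 5),
    ("10/07", 74, 16, 3), ("10/08", 496, 243, 232), ("10/09", 347, 107, 49),
    ("10/13", 157, 32, 10), ("10/14", 76, 29, 4),
]

_PROX_FLIGHT = [
    # (proximity, flight, with_acoustics, without_acoustics)
    ("near", "straight", 153, 114), ("near", "curved", 116, 29),
    ("near", "erratic", 15, 7),
    ("mid", "straight", 22, 122), ("mid", "curved", 45, 78),
    ("mid", "erratic", 9, 33),
    ("far", "straight", 5, 0), ("far", "curved", 11, 11),
    ("far", "erratic", 7, 7),
]

_INTERACTION = [
    # (proximity, interaction, with_acoustics, without_acoustics)
    ("near", "agonistic", 0, 0), ("near", "noninteracting", 0, 6),
    ("mid", "agonistic", 1, 2), ("mid", "noninteracting", 3, 11),
    ("far", "agonistic", 1, 1), ("far", "noninteracting", 1, 1),
]

_CALL_SUMMARY = {
    # row -> (ipi_ms, rate_hz, duration_ms, fstart_khz, fpeak_khz,
    #         fend_khz, bandwidth_khz, modulation_pct)
    "mean":   (217, 6.7, 6.9, 35.6, 29.3, 26.3, 10.1, 25.7),
    "sd":     (98, 2.3, 3.5, 8.5, 5.0, 3.7, 6.7, 11.0),
    "se":     (5, 0.1, 0.2, 0.4, 0.2, 0.2, 0.3, 0.5),
    "min":    (81, 2.6, 1, 23.3, 21.8, 11.3, 0.8, 2.8),
    "q1":     (140, 4.9, 4, 29.3, 25.5, 23.3, 5.3, 18.4),
    "median": (191, 6.7, 7, 33.4, 28.5, 26.3, 8.3, 24.3),
    "q3":     (271, 8.4, 9, 39.0, 31.5, 28.5, 12.0, 31.8),
    "max":    (680, 12.3, 21, 64.5, 55.5, 44.3, 38.3, 69.9),
}

N_CALL_PULSES = 584
N_CALL_FILES = 109


def nightly_counts() -> pd.DataFrame:
    """Per-night acoustic, visual and synchronous detection counts."""
    return pd.DataFrame(_NIGHTLY,
                        columns=["night", "acoustic_n", "visual_n", "synchronous_n"])


def proximity_flight_counts() -> pd.DataFrame:
    """Visual detections with/without acoustics by proximity and flight."""
    return pd.DataFrame(_PROX_FLIGHT, columns=["proximity", "flight",
                                               "with_acoustics", "without_acoustics"])


def interaction_counts() -> pd.DataFrame:
    """Multi-bat visual detections with/without acoustics by interaction."""
    return pd.DataFrame(_INTERACTION, columns=["proximity", "interaction",
                                               "with_acoustics", "without_acoustics"])


def call_metric_summary() -> pd.DataFrame:
    """Summary statistics of the 584 measured search-phase pulses."""
    cols = ["ipi_ms", "rate_hz", "duration_ms", "fstart_khz", "fpeak_khz",
            "fend_khz", "bandwidth_khz", "modulation_pct"]
    return pd.DataFrame.from_dict(_CALL_SUMMARY, orient="index", columns=cols)


def events_from_counts(counts: pd.DataFrame, label_col: str) -> pd.DataFrame:
    """Expand a count table into one labeled row per visual event.

    Each (proximity, label) cell becomes ``with_acoustics`` rows with
    synchronous=True and ``without_acoustics`` rows with False, giving the
    per-event frame the table-building code consumes.
    """
    rows = []
    for rec in counts.itertuples():
        for sync, n in ((True, rec.with_acoustics), (False, rec.without_acoustics)):
            rows.extend({"proximity": rec.proximity,
                         label_col: getattr(rec, label_col),
                         "synchronous": sync} for _ in range(int(n)))
    df = pd.DataFrame(rows)
    df["synchronous"] = df["synchronous"].astype(bool)
    return df


def total_visual_detections() -> int:
    return int(nightly_counts()["visual_n"].sum())


def multi_bat_event_count() -> int:
    """Events with more than one bat visible (26 two-bat + 1 three-bat)."""
    df = interaction_counts()
    return int((df["with_acoustics"] + df["without_acoustics"]).sum())
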