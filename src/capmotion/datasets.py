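"""Reference constants of the tracked cap-mesenchyme dataset.

The analysis this package implements was developed around a manually
tracked dataset of cap mesenchyme cells in cultured embryonic mouse
kidneys (nine samples imaged at 15- or 20-minute intervals for up to 18
hours).  The published per-sample summary and the published fit of the
distance model are kept here as reference values: the raw tables
themselves are distributed as journal supplementary material and are not
bundled, so these constants serve documentation, cross-checks and
default parameter choices.
"""

from __future__ import annotations

import pandas as pd

from .model import KProfile


def tracked_dataset_summary() -> pd.DataFrame:
    """Published per-sample summary of the tracked dataset.

    Columns: sample id, number of crops, time step (minutes), experiment
    duration (hours), tracks (possibly branched), analysis tracks
    (unbranched) and total observations (spots).
    """
    rows = [
        ("1", 1, 15, 11.75, 1, 3, 95),
        ("4", 1, 15, 12.00, 102, 118, 3753),
        ("5", 1, 15, 17.25, 5, 9, 474),
        ("6", 1, 15, 18.00, 10, 14, 707),
        ("11", 5, 15, 16.25, 249, 281, 8593),
        ("13", 1, 20, 18.67, 38, 92, 2262),
        ("14", 1, 20, 18.00, 47, 77, 1917),
        ("16", 4, 20, 18.00, 125, 189, 5295),
        ("17", 4, 20, 17.67, 47, 69, 2391),
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "crops", "step_minutes", "duration_hours", "tracks",
                 "unbranched_segments", "spots"],
    )


#: attachment annotation covered samples 13 and 14 (see the summary table)
ANNOTATED_SPOTS = 2922
ANNOTATED_SPOTS_HORIZONTAL = 1975
ATTACHMENT_INTERVALS = 25
ATTACHMENT_TRACKS = 23

#: published four-parameter fit (estimate, standard error) of k(d) = v(d)/D
PUBLISHED_FIT = {
    "d1": (0.005, 0.381),
    "d2": (14.95, 0.18),
    "k1": (0.293, 0.010),
    "k2": (-0.098, 0.001),
}

#: published simplified profile: k falls linearly from k1 at the tip surface
#: to k2 at d2, i.e. k(d) = 0.293 - 0.026 d for d <= 14.95, -0.098 beyond
PUBLISHED_SIMPLIFIED_PROFILE = KProfile(0.0, 14.95, 0.293, -0.098)
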