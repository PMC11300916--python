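"""Small curated reference datasets.

Numbers here are inputs for worked examples and cross-checks, not outputs
of this package.
"""

from __future__ import annotations

import pandas as pd


def cell_line_growth_metrics() -> pd.DataFrame:
    """Growth metrics for seven cancer cell lines used in tube-formation
    assays: estimated doubling time (hours) and the estimated time window
    (hours post seeding) over which each line's pseudo-vascular network
    exists.

    The panel spans brain (U87MG), breast (MDA-MB-231, 4T1 and the
    VM-competent derivative 4T1-T), head-and-neck (MOC1, MOC2) and
    melanoma (B16-F10) lines.  Faster-growing lines form their networks
    earlier and more transiently, which is why doubling time and window
    location track each other.
    """
    rows = [
        ("U87MG", 30.0, 7.0, 33.0),
        ("MDA-MB-231", 30.4, 8.0, 40.0),
        ("4T1", 12.5, 3.0, 15.0),
        ("4T1-T", 13.4, 3.0, 15.0),
        ("MOC1", 14.7, 8.0, 12.0),
        ("MOC2", 13.9, 4.0, 12.0),
        ("B16-F10", 24.0, 17.0, 29.0),
    ]
    return pd.DataFrame(rows, columns=["cell_line", "doubling_time_h", "t_l", "t_u"])
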