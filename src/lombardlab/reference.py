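"""Published summary tables from the tamarin noise-playback study this
package models, used as worked-example inputs and generator scenarios.

Only printed summary values exist (the raw recordings were never deposited):
per-subject call counts, mean chirp durations by treatment, and per-subject
control/treatment minimum fundamental frequencies.  The printed Δ column of
the minimum-f0 table was rounded from unrounded means, so it can differ by
±1 Hz from the exact subtraction of the printed pair.
"""

from __future__ import annotations

import pandas as pd

#: calls produced per subject during test periods (control vs treatment trials)
CALL_COUNTS = {
    "CLC": {"Bart": {"control": 23, "treatment": 24},
            "Jerry": {"control": 18, "treatment": 30},
            "Mulva": {"control": 33, "treatment": 31}},
    "chirp": {"Bart": {"control": 91, "treatment": 77},
              "Milhouse": {"control": 245, "treatment": 185},
              "Susan": {"control": 156, "treatment": 79}},
}


def total_calls(call_type: str) -> int:
    """Total calls of a type across subjects and trial types."""
    per = CALL_COUNTS[call_type]
    return sum(v for subj in per.values() for v in subj.values())


#: mean chirp duration (ms) per subject: control plus treatments A–F
#: (None = subject produced no chirps during that treatment)
CHIRP_DURATION_MS = {
    "Bart": {"control": 53.7, "A": None, "B": 64.2, "C": 54.2, "D": 58.7, "E": 59.3, "F": None},
    "Milhouse": {"control": 60.0, "A": 61.1, "B": 59.5, "C": 58.8, "D": 65.7, "E": 76.3, "F": 64.9},
    "Susan": {"control": 60.6, "A": 76.3, "B": 59.9, "C": 60.1, "D": 67.4, "E": 65.0, "F": 74.9},
}

#: minimum fundamental frequency of long calls (Hz):
#: (subject, treatment) -> (control value, treatment value, printed Δ)
MIN_F0_TABLE = {
    ("Bart", "A"): (1511, 1564, 53),
    ("Bart", "B"): (1393, 1507, 114),
    ("Bart", "C"): (1423, 1499, 77),
    ("Bart", "D"): (1553, 1497, -57),
    ("Bart", "E"): (1568, 1557, -11),
    ("Bart", "F"): (1478, 1409, -69),
    ("Jerry", "A"): (1579, 2508, 929),
    ("Jerry", "B"): (1488, 1496, 9),
    ("Jerry", "C"): (1536, 1505, -30),
    ("Jerry", "D"): (1653, 1418, -236),
    ("Jerry", "E"): (1489, 1444, -45),
    ("Jerry", "F"): (1693, 1545, -148),
    ("Mulva", "A"): (1653, 1761, 107),
    ("Mulva", "B"): (1716, 1656, -59),
    ("Mulva", "C"): (1564, 1631, 67),
    ("Mulva", "D"): (1674, 1618, -56),
    ("Mulva", "E"): (1671, 1597, -74),
    ("Mulva", "F"): (1649, 1659, 11),
}


def min_f0_summaries() -> pd.DataFrame:
    """The printed control/treatment minimum-f0 pairs as a trial-summary
    table suitable for :func:`lombardlab.stats.delta_table`.

    The published control column is session-paired: each treatment row
    carries the control value from the session in which that treatment was
    presented, so the table expands to one control and one treatment row per
    session.
    """
    rows = []
    for (subject, treatment), (ctrl, treat, _) in sorted(MIN_F0_TABLE.items()):
        session = ord(treatment) - ord("A") + 1
        rows.append({"subject": subject, "session": session,
                     "trial_id": f"{subject}_s{session}_control",
                     "trial_type": "control", "treatment": "none",
                     "call_type": "CLC", "min_f0": float(ctrl)})
        rows.append({"subject": subject, "session": session,
                     "trial_id": f"{subject}_s{session}_{treatment}",
                     "trial_type": "treatment", "treatment": treatment,
                     "call_type": "CLC", "min_f0": float(treat)})
    return pd.DataFrame(rows)
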