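"""Independent brute-force oracles for the staging logic.

Deliberately written in a different style from the package (character
strings and repeated full re-scans) so that agreement with the streaming
implementation is meaningful.
"""

from __future__ import annotations

import numpy as np


def oracle_stage(active, immobility_min_s: int = 40, merge_filter_s: int = 15):
    """Reference sleep/wake labeling of a per-second binary activity trace.

    Returns an array over {"Sleep", "Wake"}. Sleep = any maximal run of
    zeros with length >= immobility_min_s; then every Wake run of length
    <= merge_filter_s with Sleep immediately on both sides is relabeled,
    re-scanning from scratch until nothing changes.
    """
    s = "".join("W" if a else "i" for a in active)
    out = list(s)
    n = len(out)
    i = 0
    while i < n:
        if out[i] == "i":
            j = i
            while j < n and out[j] == "i":
                j += 1
            fill = "S" if (j - i) >= immobility_min_s else "W"
            for k in range(i, j):
                out[k] = fill
            i = j
        else:
            i += 1
    if merge_filter_s > 0:
        changed = True
        while changed:
            changed = False
            i = 0
            while i < n:
                if out[i] == "W":
                    j = i
                    while j < n and out[j] == "W":
                        j += 1
                    if (j - i) <= merge_filter_s and i > 0 and j < n \
                            and out[i - 1] == "S" and out[j] == "S":
                        for k in range(i, j):
                            out[k] = "S"
                        changed = True
                    i = j
                else:
                    i += 1
    return np.array(["Sleep" if c == "S" else "Wake" for c in out], dtype="U8")


def oracle_epoch(labels, epoch_s: int = 20):
    """Majority vote per epoch, ties to Wake, trailing partial dropped."""
    out = []
    for start in range(0, (len(labels) // epoch_s) * epoch_s, epoch_s):
        chunk = list(labels[start:start + epoch_s])
        n_sleep = chunk.count("Sleep")
        out.append("Sleep" if n_sleep > len(chunk) - n_sleep else "Wake")
    return np.array(out, dtype="U8")
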