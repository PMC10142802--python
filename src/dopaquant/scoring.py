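"""Final uptake ratios.

The selected lesion maximum (read on the raw PET) divided by the
normal-tissue mean c_n gives the tumor-to-normal score t_n, and divided by
the striatal mean c_s gives the tumor-to-striatum score t_s — identical to
reading the maximum on the normalized images P_n and P_s. Both ratios are
invariant to any global rescaling of the PET (dose/weight factors cancel),
which is why relative activities suffice throughout.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ScorePair:
    t_n: float
    t_s: float

    def __post_init__(self) -> None:
        if not (self.t_n > 0 and self.t_s > 0):
            raise ValueError("scores must be positive")


def compute_scores(max_value: float, c_n: float, c_s: float) -> ScorePair:
    """t_n = max/c_n, t_s = max/c_s for positive normalization constants."""
    if not c_n > 0:
        raise ValueError("c_n must be > 0")
    if not c_s > 0:
        raise ValueError("c_s must be > 0")
    return ScorePair(t_n=max_value / c_n, t_s=max_value / c_s)
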