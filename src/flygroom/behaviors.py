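"""Behavior label alphabet and the analysis clock.

The classifier works with three classes (grooming, locomotion, rest);
the full ethogram refines rest into short rest and sleep and overlays
feeding, giving five mutually exclusive behaviors per frame.
"""
from __future__ import annotations

from dataclasses import dataclass

GROOMING = "grooming"
LOCOMOTION = "locomotion"
REST = "rest"
FEEDING = "feeding"
SHORT_REST = "short_rest"
SLEEP = "sleep"

#: The three classes the kNN classifier distinguishes, in the fixed order
#: used to break classification ties deterministically.
CLASSIFIER_CLASSES = (GROOMING, LOCOMOTION, REST)

#: The five classes of the assembled ethogram.
ETHOGRAM_CLASSES = (GROOMING, LOCOMOTION, FEEDING, SHORT_REST, SLEEP)

#: Wake is the complement of sleep.
WAKE_CLASSES = (GROOMING, LOCOMOTION, FEEDING, SHORT_REST)


@dataclass(frozen=True)
class AnalysisClock:
    """Mapping between native video frames and analyzed frames.

    Videos are recorded at ``native_rate`` (10 Hz by default) but features
    are computed on every ``stride``-th frame, i.e. at 5 Hz, which is
    sufficient to resolve grooming leg movements.
    """

    native_rate: float = 10.0
    stride: int = 2

    @property
    def analysis_rate(self) -> float:
        return self.native_rate / self.stride

    def native_index(self, analyzed_index: int) -> int:
        """Native frame index of the given analyzed frame."""
        return analyzed_index * self.stride

    def n_analyzed(self, n_native: int) -> int:
        """Number of analyzed frames in a video of ``n_native`` frames."""
        return (n_native + self.stride - 1) // self.stride

    def analyzed_seconds(self, n_analyzed_frames: int) -> float:
        return n_analyzed_frames / self.analysis_rate
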