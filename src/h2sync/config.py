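"""Analysis configuration shared by every pipeline stage.

The defaults reproduce the study conditions: 256 Hz sampling, 2 s analysis
windows sliding in 1 s steps, a 0.4 threshold on h2 for counting a directed
connection, 3 s peak-centred averaging for the synchronization indices, and
15 s periods of interest at seizure onset and end.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the sliding-window h2 connectivity analysis.

    Attributes
    ----------
    window_s : float
        Length of each analysis window in seconds.
    step_s : float
        Step between successive window starts in seconds.
    h2_threshold : float
        An edge contributes to in/out degrees only if its h2 exceeds this.
    peak_avg_s : float
        Width of the averaging span centred on a measure's peak when a
        period index is computed.
    period_len_s : float
        Length of the seizure-onset and end-of-seizure periods.
    n_bins : int
        Number of equal-width amplitude bins of the piecewise-linear fit.
    max_delay_s : float
        Half-range of the delay scan, in seconds, per direction.
    rate : float
        Sampling rate in Hz the configuration is intended for (used only to
        convert ``max_delay_s`` to samples; the actual recording rate wins
        when they differ).
    """

    window_s: float = 2.0
    step_s: float = 1.0
    h2_threshold: float = 0.4
    peak_avg_s: float = 3.0
    period_len_s: float = 15.0
    n_bins: int = 10
    max_delay_s: float = 0.1
    rate: float = 256.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if not 0.0 <= self.h2_threshold <= 1.0:
            raise ValueError("h2_threshold must lie in [0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.max_delay_s * self.rate < 1:
            raise ValueError("max_delay_s must span at least one sample")

    def max_delay_samples(self, rate: float | None = None) -> int:
        """Delay-scan range in samples at the given (or configured) rate."""
        r = self.rate if rate is None else rate
        return int(round(self.max_delay_s * r))


DEFAULT_CONFIG = AnalysisConfig()
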