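"""Stimulus metadata for steady-state pattern-reversal stimulation.

A steady-state PERG is evoked by a checkerboard whose black and white
checks swap at a fixed reversal rate.  Each reversal drives one response
cycle, so the fundamental frequency of the steady-state response (in Hz)
equals the reversal rate (in reversals per second, rps).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition: check size (deg of visual angle) x reversal rate (rps)."""

    check_size_deg: float
    reversal_rate_rps: float

    def __post_init__(self) -> None:
        if self.check_size_deg <= 0:
            raise ValueError(f"check_size_deg must be > 0, got {self.check_size_deg}")
        if self.reversal_rate_rps <= 0:
            raise ValueError(
                f"reversal_rate_rps must be > 0, got {self.reversal_rate_rps}"
            )

    @property
    def frequency_hz(self) -> float:
        """Fundamental analysis frequency: one response cycle per reversal."""
        return self.reversal_rate_rps

    @property
    def period_ms(self) -> float:
        """Stimulus period in milliseconds (1000 / reversal rate)."""
        return 1000.0 / self.reversal_rate_rps

    def bin_index(self, sweep_length_s: float, tol: float = 1e-9) -> int:
        """DFT bin of the fundamental for a sweep of ``sweep_length_s`` seconds.

        The analysis frequency must be bin aligned: ``rate x sweep_length``
        an integer (e.g. 12.5 rps x 0.96 s = bin 12), otherwise the sweep
        does not contain a whole number of response cycles and the DFT
        would leak.
        """
        k = self.reversal_rate_rps * sweep_length_s
        k_round = round(k)
        if abs(k - k_round) > tol or k_round < 1:
            lo = int(k) / sweep_length_s
            hi = (int(k) + 1) / sweep_length_s
            raise ValueError(
                f"reversal rate {self.reversal_rate_rps} rps is not bin aligned for a "
                f"{sweep_length_s} s sweep (rate x length = {k}); nearest aligned "
                f"frequencies are {lo:g} and {hi:g} Hz"
            )
        return int(k_round)

    def label(self) -> str:
        """Compact condition label, e.g. ``0.8deg_12.5rps``."""
        return f"{self.check_size_deg:g}deg_{self.reversal_rate_rps:g}rps"
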