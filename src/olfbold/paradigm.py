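"""Block-design stimulation schedules.

The paradigm of interest is an odor block design: an initial odorless
(stimulus-off) period followed by ``n_blocks`` repetitions of a stimulus-on
period and a stimulus-off period.  During each on period the odorant is
delivered as a train of short pulses (e.g. 1 s odorant / 2 s odorless
carrier), but for analysis the on period is treated as one sustained
condition.  The schedule also carries the per-volume ON/OFF labels and the
window logic used by the ΔS/S estimator (stimulus-on windows, and the
second half of the stimulus-off period preceding each block as baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParadigmSchedule", "build_paradigm"]

#: tolerance (in samples) when checking that the total duration is a whole
#: number of repetition times
_DIVISIBILITY_TOL = 1e-6


@dataclass(frozen=True)
class ParadigmSchedule:
    """Timing of a block-design stimulation paradigm, sampled per volume.

    Volume ``i`` is taken to be acquired at ``t = i * tr_seconds`` with the
    first volume at ``t = 0``.  ``block_index`` assigns 0 to the pre-stimulus
    period and ``b`` (1-based) to block ``b``'s on period *and* the off
    period that follows it.
    """

    tr_seconds: float
    n_volumes: int
    initial_off_seconds: float
    n_blocks: int
    on_seconds: float
    off_seconds: float
    pulse_on_seconds: float
    pulse_off_seconds: float
    labels: np.ndarray = field(repr=False)          # '<U3' array, 'ON'/'OFF'
    block_index: np.ndarray = field(repr=False)     # int array, 0..n_blocks
    pulse_train: tuple = field(repr=False)          # ((onset_s, duration_s), ...)

    # ------------------------------------------------------------------ basics
    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each volume in seconds."""
        return np.arange(self.n_volumes) * self.tr_seconds

    @property
    def total_seconds(self) -> float:
        return self.initial_off_seconds + self.n_blocks * (
            self.on_seconds + self.off_seconds
        )

    @property
    def pulses_per_block(self) -> int:
        return int(
            np.floor(
                self.on_seconds / (self.pulse_on_seconds + self.pulse_off_seconds)
            )
        )

    @property
    def is_on(self) -> np.ndarray:
        return self.labels == "ON"

    def block_start(self, block: int) -> float:
        """Start time (s) of block ``block``'s stimulus-on period (1-based)."""
        self._check_block(block)
        return self.initial_off_seconds + (block - 1) * (
            self.on_seconds + self.off_seconds
        )

    def _check_block(self, block: int) -> None:
        if not 1 <= block <= self.n_blocks:
            raise ValueError(
                f"block must be in 1..{self.n_blocks}, got {block}"
            )

    # ------------------------------------------------------------- window logic
    def on_volume_mask(self, block: int | None = None, delay_s: float = 0.0) -> np.ndarray:
        """Boolean mask of volumes sampling a stimulus-on period.

        ``delay_s`` shifts the windows forward in acquisition time to account
        for hemodynamic lag: volume ``i`` is assigned to the paradigm state at
        ``t_i - delay_s``.
        """
        if delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        t = self.times - delay_s
        blocks = range(1, self.n_blocks + 1) if block is None else (block,)
        mask = np.zeros(self.n_volumes, dtype=bool)
        for b in blocks:
            s = self.block_start(b)
            mask |= (t >= s) & (t < s + self.on_seconds)
        return mask

    def baseline_volume_mask(
        self,
        block: int,
        delay_s: float = 0.0,
        rule: str = "preceding",
    ) -> np.ndarray:
        """Volumes in the second half of the off period used as ΔS/S baseline.

        Only the second half of the stimulus-off period is used, because the
        post-stimulus transition can occupy 50-100% of the stimulus-on
        duration.  ``rule='preceding'`` (default) takes the off period before
        the block (the initial off period precedes block 1);
        ``rule='following'`` takes the off period after the block's on period.
        """
        if delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        self._check_block(block)
        if rule == "preceding":
            if block == 1:
                lo, hi = 0.0, self.initial_off_seconds
            else:
                lo = self.block_start(block - 1) + self.on_seconds
                hi = lo + self.off_seconds
        elif rule == "following":
            lo = self.block_start(block) + self.on_seconds
            hi = lo + self.off_seconds
        else:
            raise ValueError(f"unknown baseline rule {rule!r}")
        lo = lo + (hi - lo) / 2.0  # second half only
        t = self.times - delay_s
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(
                f"baseline window for block {block} ({rule} off period) contains "
                "no volumes; schedule is degenerate for ΔS/S"
            )
        return mask

    # ----------------------------------------------------------------- export
    def to_frame(self):
        """Per-volume table (volume_index, time_s, label, block_index)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "volume_index": np.arange(self.n_volumes),
                "time_s": self.times,
                "label": self.labels,
                "block_index": self.block_index,
            }
        )


def build_paradigm(
    tr_seconds: float,
    initial_off_seconds: float,
    n_blocks: int,
    on_seconds: float,
    off_seconds: float,
    pulse_on_seconds: float,
    pulse_off_seconds: float,
) -> ParadigmSchedule:
    """Construct a pulsed block-design schedule.

    The default olfactory paradigm is ``build_paradigm(2, 60, 3, 60, 120, 1, 2)``:
    60 s off, then three blocks of 60 s on (20 pulses of 1 s odorant + 2 s
    odorless carrier) + 120 s off; 600 s and 300 volumes in total.

    Raises
    ------
    ValueError
        If any duration is invalid, ``n_blocks`` < 1, or the total duration is
        not a whole number of repetition times.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if initial_off_seconds < 0:
        raise ValueError("initial_off_seconds must be non-negative")
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1 (zero blocks rejected)")
    for name, v in [
        ("on_seconds", on_seconds),
        ("off_seconds", off_seconds),
        ("pulse_on_seconds", pulse_on_seconds),
        ("pulse_off_seconds", pulse_off_seconds),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    total = initial_off_seconds + n_blocks * (on_seconds + off_seconds)
    n_float = total / tr_seconds
    n_volumes = int(round(n_float))
    if abs(n_float - n_volumes) > _DIVISIBILITY_TOL:
        raise ValueError(
            f"total paradigm duration {total} s is not divisible by "
            f"tr_seconds={tr_seconds} s ({n_float} volumes); adjust the block "
            "durations or the repetition time"
        )

    t = np.arange(n_volumes) * tr_seconds
    cycle = on_seconds + off_seconds
    labels = np.full(n_volumes, "OFF", dtype="<U3")
    block_index = np.zeros(n_volumes, dtype=int)
    pulse_period = pulse_on_seconds + pulse_off_seconds
    n_pulses = int(np.floor(on_seconds / pulse_period))
    pulses = []
    for b in range(1, n_blocks + 1):
        start = initial_off_seconds + (b - 1) * cycle
        labels[(t >= start) & (t < start + on_seconds)] = "ON"
        block_index[(t >= start) & (t < start + cycle)] = b
        for k in range(n_pulses):
            pulses.append((start + k * pulse_period, pulse_on_seconds))

    return ParadigmSchedule(
        tr_seconds=float(tr_seconds),
        n_volumes=n_volumes,
        initial_off_seconds=float(initial_off_seconds),
        n_blocks=int(n_blocks),
        on_seconds=float(on_seconds),
        off_seconds=float(off_seconds),
        pulse_on_seconds=float(pulse_on_seconds),
        pulse_off_seconds=float(pulse_off_seconds),
        labels=labels,
        block_index=block_index,
        pulse_train=tuple(pulses),
    )
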