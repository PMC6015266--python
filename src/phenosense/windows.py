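"""Clock-time analysis windows.

Features are extracted within recurring daily windows: daytime (09:00-18:00),
evening (18:00-24:00), late night (00:00-03:00), the per-day sleep interval,
and the full civil day. Bounds are half-open ``[start, end)`` local time.
"""

from __future__ import annotations

from enum import Enum


class Window(Enum):
    """A recurring daily time-of-day window.

    ``SLEEP`` has no fixed clock bounds; it refers to per-participant,
    per-day sleep intervals supplied alongside the sensor data.
    """

    DAY = ("day", 9.0, 18.0)
    NIGHT = ("night", 18.0, 24.0)
    LATE_NIGHT = ("late_night", 0.0, 3.0)
    FULL_DAY = ("full_day", 0.0, 24.0)
    SLEEP = ("sleep", None, None)

    def __init__(self, label: str, start_hour: float | None, end_hour: float | None):
        self.label = label
        self.start_hour = start_hour
        self.end_hour = end_hour

    @property
    def clock_bounded(self) -> bool:
        return self.start_hour is not None

    def bounds_seconds(self) -> tuple[int, int]:
        """Window bounds as seconds since local midnight (half-open)."""
        if not self.clock_bounded:
            raise ValueError("SLEEP window has no fixed clock bounds")
        return int(self.start_hour * 3600), int(self.end_hour * 3600)


#: windows used for the wearable-sensor feature block
SENSOR_WINDOWS = (Window.LATE_NIGHT, Window.SLEEP, Window.DAY, Window.NIGHT)

#: windows used for the phone event feature block
PHONE_WINDOWS = (Window.FULL_DAY, Window.LATE_NIGHT, Window.NIGHT)
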