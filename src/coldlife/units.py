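"""Unit helpers. Internally everything is hours and Kelvin."""

CELSIUS_OFFSET = 273.15
HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.0
GAS_CONSTANT = 8.31446261815324  # J / (mol K)


def kelvin(celsius: float) -> float:
    """Convert a temperature from degrees Celsius to Kelvin."""
    return celsius + CELSIUS_OFFSET


def celsius(kelvin_: float) -> float:
    """Convert a temperature from Kelvin to degrees Celsius."""
    return kelvin_ - CELSIUS_OFFSET


def hours(days: float) -> float:
    """Convert days to hours."""
    return days * HOURS_PER_DAY


def days(hours_: float) -> float:
    """Convert hours to days."""
    return hours_ / HOURS_PER_DAY


def years(hours_: float) -> float:
    """Convert hours to years (365-day year)."""
    return hours_ / (HOURS_PER_DAY * DAYS_PER_YEAR)
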