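"""Interpretation of MRA (modified 3' RACE) band patterns.

The assay produces, per locus, two nested-PCR lanes (P-4a from the
forward-priming reaction, P-4b from the reverse-priming reaction) and a
template control lane (P-c). Presence of a band at the predicted size in
P-4a and/or P-4b indicates which strand(s) the locus is transcribed from:

    P-4a  P-4b   call
     +     -     F   (forward only)
     -     +     R   (reverse only)
     +     +     FR  (bidirectional)
     -     -     NONE (transcript undetected; control still valid)

A missing control band invalidates the lane set (no call). Bands outside
the size tolerance are flagged as nonspecific amplification and do not
count as presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InvalidControlError, ValidationError
from .io_formats import BandRow

DEFAULT_TOLERANCE = 0.2  # fraction of expected size; gel-resolution scale

LANES = ("P4a", "P4b", "Pc")


@dataclass(frozen=True)
class BandLane:
    """Observed band sizes in one lane against its predicted size."""

    lane_id: str
    observed_band_sizes: tuple[float, ...]
    expected_size: int

    def __post_init__(self) -> None:
        if self.lane_id not in LANES:
            raise ValidationError(f"unknown lane {self.lane_id!r}")
        if self.expected_size <= 0:
            raise ValidationError("expected_size must be positive")
        if any(s <= 0 for s in self.observed_band_sizes):
            raise ValidationError("band sizes must be positive")


@dataclass(frozen=True)
class BandCall:
    present: bool
    nonspecific: bool  # extra band(s) outside tolerance observed


@dataclass(frozen=True)
class OrientationCall:
    """Transcription-orientation call for one locus (one sample)."""

    call: str  # F, R, FR or NONE
    nonspecific: bool = False

    def __post_init__(self) -> None:
        if self.call not in {"F", "R", "FR", "NONE"}:
            raise ValidationError(f"bad orientation call {self.call!r}")


def call_band(
    lane: BandLane, tolerance_fraction: float = DEFAULT_TOLERANCE
) -> BandCall:
    """Judge band presence by size match within a fractional tolerance."""
    if not (0 < tolerance_fraction < 1):
        raise ValidationError("tolerance_fraction must lie in (0, 1)")
    tol = tolerance_fraction * lane.expected_size
    present = any(
        abs(s - lane.expected_size) <= tol for s in lane.observed_band_sizes
    )
    nonspecific = any(
        abs(s - lane.expected_size) > tol for s in lane.observed_band_sizes
    )
    return BandCall(present=present, nonspecific=nonspecific)


def interpret_pattern(p4a: bool, p4b: bool, pc: bool) -> OrientationCall:
    """Map a (P-4a, P-4b, P-c) presence pattern to an orientation call."""
    if not pc:
        raise InvalidControlError(
            "template control band P-c absent; no orientation call possible"
        )
    call = {(True, False): "F", (False, True): "R",
            (True, True): "FR", (False, False): "NONE"}[(p4a, p4b)]
    return OrientationCall(call=call)


def stage_consistency(calls: Mapping[str, OrientationCall | str]) -> str:
    """Summarize per-stage orientation calls for one locus.

    Returns one of ``bidirectional_all_stages``,
    ``bidirectional_some_stages``, ``unidirectional_consistent`` or
    ``mixed``.
    """
    if not calls:
        raise ValidationError("no stage calls supplied")
    vals = [getattr(c, "call", c) for c in calls.values()]
    if any(v == "FR" for v in vals):
        return (
            "bidirectional_all_stages"
            if all(v == "FR" for v in vals)
            else "bidirectional_some_stages"
        )
    if len(set(vals)) == 1 and vals[0] in {"F", "R"}:
        return "unidirectional_consistent"
    return "mixed"


def calls_from_band_table(
    rows: Sequence[BandRow],
    tolerance_fraction: float = DEFAULT_TOLERANCE,
) -> dict[tuple[str, str], OrientationCall]:
    """Group band-table rows by (lincRNA, stage) and call each group.

    Each group must contain all three lanes. Nonspecific extra bands in any
    lane set the call's nonspecific flag.
    """
    groups: dict[tuple[str, str], dict[str, BandRow]] = {}
    for r in rows:
        groups.setdefault((r.lincrna_id, r.stage), {})[r.lane] = r

    out: dict[tuple[str, str], OrientationCall] = {}
    for key, lanes in sorted(groups.items()):
        missing = set(LANES) - set(lanes)
        if missing:
            raise ValidationError(
                f"lincRNA {key[0]} stage {key[1]}: missing lane(s) "
                f"{sorted(missing)}"
            )
        band_calls = {
            lane: call_band(
                BandLane(lane, lanes[lane].observed_sizes,
                         lanes[lane].expected_size),
                tolerance_fraction,
            )
            for lane in LANES
        }
        call = interpret_pattern(
            band_calls["P4a"].present,
            band_calls["P4b"].present,
            band_calls["Pc"].present,
        )
        if any(bc.nonspecific for bc in band_calls.values()):
            call = OrientationCall(call=call.call, nonspecific=True)
        out[key] = call
    return out
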