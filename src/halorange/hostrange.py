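"""Plaque-confirmed virus-host interaction matrices and efficiency of plating.

A spot-on-lawn screen of haloarchaeal virus lysates can show growth inhibition
for two reasons: productive infection, or halocins (antimicrobial proteins)
contaminating the lysate. Only plaque formation in the quantitative double-layer
assay confirms a true virus-host pair, so the interaction call logic here treats
spot-only inhibition as ``halocin_suspect``, never as positive.

Titers are in pfu/mL. The efficiency of plating (EOP) of a virus on a test host
is its plaque titer there divided by its titer on the reference (isolation)
host; an EOP of 1 means equal plating efficiency. EOPs are conventionally
reported to one significant figure.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Assay",
    "Call",
    "TiterObservation",
    "InteractionCall",
    "EOPRecord",
    "VirusRecord",
    "HostRangeMatrix",
    "parse_titer",
    "call_interaction",
    "compute_eop",
    "round_one_significant",
    "load_lr25_screen",
]


class Assay(str, enum.Enum):
    SPOT = "spot"
    PLAQUE = "plaque"


class Call(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    HALOCIN_SUSPECT = "halocin_suspect"
    UNTESTED = "untested"


#: sentinel titer states in input tables
_BELOW_DETECTION = frozenset({"-", ""})
_UNTESTED = frozenset({"nd", "n.d.", "na", "n/a"})

# "1.2e9", "1.2E9", "1.2 × 10^9", "1.2 x 10^9", "3", "0.2"
_SCI_X10 = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*[x×]\s*10\s*\^?\s*([+-]?[0-9]+)\s*$", re.IGNORECASE
)


def parse_titer(cell: str | float | int | None) -> tuple[float | None, str]:
    """Parse a titer cell into ``(value, status)``.

    status is one of ``"value"`` (value is a finite non-negative float),
    ``"below_detection"`` (``-`` cells) or ``"untested"`` (``nd`` cells).
    Accepts plain/scientific notation ``1.2e9`` as well as ``1.2 × 10^9``.
    """
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None, "untested"
    if isinstance(cell, (int, float)):
        value = float(cell)
    else:
        text = str(cell).strip()
        low = text.lower()
        if low in _UNTESTED:
            return None, "untested"
        if low in _BELOW_DETECTION:
            return None, "below_detection"
        m = _SCI_X10.match(text)
        if m:
            value = float(m.group(1)) * 10.0 ** int(m.group(2))
        else:
            try:
                value = float(text)
            except ValueError as exc:
                raise ValueError(f"unparseable titer cell: {cell!r}") from exc
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"titer must be finite and non-negative, got {value!r}")
    return value, "value"


@dataclass(frozen=True)
class TiterObservation:
    """One titer measurement (or explicit non-detection) for a virus-host pair."""

    virus_id: str
    host_id: str
    titer: float | None  # pfu/mL; None when below detection
    assay: Assay = Assay.PLAQUE
    below_detection: bool = False

    def __post_init__(self) -> None:
        has_value = self.titer is not None
        if has_value == self.below_detection:
            raise ValueError(
                "exactly one of titer / below_detection must be set "
                f"({self.virus_id} on {self.host_id})"
            )
        if has_value and (not math.isfinite(self.titer) or self.titer < 0):
            raise ValueError(f"invalid titer {self.titer!r}")


@dataclass(frozen=True)
class InteractionCall:
    virus_id: str
    host_id: str
    spot_inhibition: bool
    plaques_observed: bool
    call: Call


def call_interaction(spot_inhibition: bool, plaques_observed: bool) -> Call:
    """Classify a virus-host pair from the two assay outcomes.

    Plaques confirm infection regardless of the spot result; an inhibition zone
    without plaques is the halocin false-positive signature and is flagged, not
    counted as positive.
    """
    if plaques_observed:
        return Call.POSITIVE
    if spot_inhibition:
        return Call.HALOCIN_SUSPECT
    return Call.NEGATIVE


def round_one_significant(x: float) -> tuple[int, int]:
    """Round ``x > 0`` to one significant figure, half away from zero.

    Returns ``(mantissa, exponent)`` with mantissa in 1..9, i.e.
    ``x ≈ mantissa * 10**exponent``.
    """
    if not (x > 0 and math.isfinite(x)):
        raise ValueError(f"need a positive finite value, got {x!r}")
    exponent = math.floor(math.log10(x))
    mantissa_f = x / 10.0**exponent
    # guard against log10 landing one decade off for values like 0.1
    if mantissa_f >= 10.0:
        mantissa_f /= 10.0
        exponent += 1
    elif mantissa_f < 1.0:
        mantissa_f *= 10.0
        exponent -= 1
    mantissa = math.floor(mantissa_f + 0.5)  # half away from zero (x > 0)
    if mantissa == 10:
        mantissa = 1
        exponent += 1
    return mantissa, exponent


def _format_one_sig(mantissa: int, exponent: int) -> str:
    return str(mantissa) if exponent == 0 else f"{mantissa}e{exponent}"


@dataclass(frozen=True)
class EOPRecord:
    """Efficiency of plating of one virus on a test host relative to a reference."""

    virus_id: str
    reference_host_id: str
    test_host_id: str
    eop_raw: float | None
    mantissa: int | None = None
    exponent: int | None = None
    #: when the test titer is below detection: detection_limit / reference titer
    upper_bound: float | None = None

    @property
    def defined(self) -> bool:
        return self.eop_raw is not None

    @property
    def formatted(self) -> str | None:
        """One-significant-figure rendering, e.g. ``'6e-6'`` or ``'3'``."""
        if self.mantissa is None:
            return None
        return _format_one_sig(self.mantissa, self.exponent)


def compute_eop(
    titer_test: float | None,
    titer_reference: float,
    *,
    virus_id: str = "",
    reference_host_id: str = "",
    test_host_id: str = "",
    detection_limit: float | None = None,
) -> EOPRecord:
    """EOP = test titer / reference titer, with one-significant-figure rounding.

    A below-detection test titer (``None``) yields an undefined EOP; if a
    detection limit is supplied, ``upper_bound = detection_limit / reference``.
    A missing or zero reference titer is an error — the ratio has no meaning.
    """
    if titer_reference is None or not (titer_reference > 0) or not math.isfinite(titer_reference):
        raise ValueError(
            f"reference titer must be positive and finite, got {titer_reference!r}"
        )
    if titer_test is None:
        ub = None if detection_limit is None else detection_limit / titer_reference
        return EOPRecord(virus_id, reference_host_id, test_host_id, None, upper_bound=ub)
    if not (titer_test > 0) or not math.isfinite(titer_test):
        raise ValueError(f"test titer must be positive and finite, got {titer_test!r}")
    raw = titer_test / titer_reference
    mantissa, exponent = round_one_significant(raw)
    return EOPRecord(virus_id, reference_host_id, test_host_id, raw, mantissa, exponent)


@dataclass(frozen=True)
class VirusRecord:
    virus_id: str
    genus: str | None = None
    family: str | None = None
    morphology: str | None = None  # "myovirus" | "siphovirus"
    own_host: str | None = None


@dataclass
class _Cell:
    call: Call
    titer: TiterObservation | None = None


class HostRangeMatrix:
    """Virus × host grid of interaction calls and plaque titers.

    Cells default to ``untested``. Identity groups (sets of virus ids whose
    genomes are known to be identical) are input metadata from sequencing, not
    computed here; they drive :meth:`dedup_unique`.
    """

    def __init__(
        self,
        viruses: Sequence[VirusRecord | str],
        hosts: Sequence[str],
        identity_groups: Iterable[Iterable[str]] = (),
    ) -> None:
        self.viruses: list[VirusRecord] = [
            v if isinstance(v, VirusRecord) else VirusRecord(v) for v in viruses
        ]
        ids = [v.virus_id for v in self.viruses]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate virus ids")
        self.hosts: list[str] = list(hosts)
        if len(set(self.hosts)) != len(self.hosts):
            raise ValueError("duplicate host ids")
        self._virus_ids = set(ids)
        self._host_ids = set(self.hosts)
        self._cells: dict[tuple[str, str], _Cell] = {}
        groups = [frozenset(g) for g in identity_groups]
        seen: set[str] = set()
        for g in groups:
            unknown = g - self._virus_ids
            if unknown:
                raise ValueError(f"identity group members not in matrix: {sorted(unknown)}")
            if g & seen:
                raise ValueError("identity groups must be disjoint")
            seen |= g
        self.identity_groups: list[frozenset[str]] = groups

    # -- construction -----------------------------------------------------

    def set_cell(
        self,
        virus_id: str,
        host_id: str,
        *,
        spot_inhibition: bool = False,
        plaques_observed: bool = False,
        titer: TiterObservation | None = None,
        untested: bool = False,
    ) -> None:
        self._check_ids(virus_id, host_id)
        if untested:
            self._cells[(virus_id, host_id)] = _Cell(Call.UNTESTED, None)
            return
        call = call_interaction(spot_inhibition, plaques_observed)
        self._cells[(virus_id, host_id)] = _Cell(call, titer)

    @classmethod
    def from_tables(
        cls,
        titers: pd.DataFrame,
        viruses: pd.DataFrame | None = None,
        identity: pd.DataFrame | None = None,
    ) -> "HostRangeMatrix":
        """Build a matrix from long-format assay tables.

        ``titers`` needs columns ``virus_id, host_id, assay, titer``. Plaque
        rows carry a titer (scientific notation accepted), ``-`` for no plaques
        at detection, or ``nd`` for untested. Spot rows use ``+``/``-`` in the
        titer column for inhibition / no inhibition. ``viruses`` optionally
        supplies genus/family/morphology/own_host metadata; ``identity`` has
        columns ``group_id, virus_id``.
        """
        required = {"virus_id", "host_id", "assay", "titer"}
        missing = required - set(titers.columns)
        if missing:
            raise ValueError(f"titer table missing columns: {sorted(missing)}")

        vrecs: dict[str, VirusRecord] = {}
        if viruses is not None:
            for row in viruses.itertuples(index=False):
                vrecs[row.virus_id] = VirusRecord(
                    row.virus_id,
                    genus=getattr(row, "genus", None),
                    family=getattr(row, "family", None),
                    morphology=getattr(row, "morphology", None),
                    own_host=getattr(row, "own_host", None),
                )
        virus_order: list[str] = list(vrecs)
        host_order: list[str] = []
        spot: dict[tuple[str, str], bool] = {}
        plaque: dict[tuple[str, str], tuple[float | None, str]] = {}
        for row in titers.itertuples(index=False):
            vid, hid = str(row.virus_id), str(row.host_id)
            if vid not in vrecs:
                vrecs[vid] = VirusRecord(vid)
                virus_order.append(vid)
            if hid not in host_order:
                host_order.append(hid)
            assay = Assay(str(row.assay).strip().lower())
            if assay is Assay.SPOT:
                mark = str(row.titer).strip()
                if mark not in {"+", "-"}:
                    raise ValueError(f"spot rows take '+'/'-', got {row.titer!r}")
                spot[(vid, hid)] = mark == "+"
            else:
                plaque[(vid, hid)] = parse_titer(row.titer)

        groups: list[frozenset[str]] = []
        if identity is not None and len(identity):
            groups = [
                frozenset(sub["virus_id"].astype(str))
                for _, sub in identity.groupby("group_id", sort=True)
            ]

        matrix = cls([vrecs[v] for v in virus_order], host_order, groups)
        for key in set(spot) | set(plaque):
            vid, hid = key
            value, status = plaque.get(key, (None, "untested"))
            spot_hit = spot.get(key, False)
            if status == "untested" and key not in spot:
                matrix.set_cell(vid, hid, untested=True)
                continue
            if status == "value":
                obs = TiterObservation(vid, hid, value, Assay.PLAQUE)
                matrix.set_cell(vid, hid, spot_inhibition=spot_hit,
                                plaques_observed=True, titer=obs)
            elif status == "below_detection":
                obs = TiterObservation(vid, hid, None, Assay.PLAQUE, below_detection=True)
                matrix.set_cell(vid, hid, spot_inhibition=spot_hit,
                                plaques_observed=False, titer=obs)
            else:  # plaque untested but a spot result exists
                matrix.set_cell(vid, hid, spot_inhibition=spot_hit,
                                plaques_observed=False)
        return matrix

    # -- queries -----------------------------------------------------------

    def _check_ids(self, virus_id: str, host_id: str) -> None:
        if virus_id not in self._virus_ids:
            raise KeyError(f"unknown virus id {virus_id!r}")
        if host_id not in self._host_ids:
            raise KeyError(f"unknown host id {host_id!r}")

    def cell(self, virus_id: str, host_id: str) -> tuple[Call, TiterObservation | None]:
        self._check_ids(virus_id, host_id)
        c = self._cells.get((virus_id, host_id))
        return (c.call, c.titer) if c else (Call.UNTESTED, None)

    def call(self, virus_id: str, host_id: str) -> Call:
        return self.cell(virus_id, host_id)[0]

    def positives(self, host_id: str) -> list[str]:
        if host_id not in self._host_ids:
            raise KeyError(f"unknown host id {host_id!r}")
        return [
            v.virus_id
            for v in self.viruses
            if self._cells.get((v.virus_id, host_id), _Cell(Call.UNTESTED)).call
            is Call.POSITIVE
        ]

    def count_positive(self, host_id: str) -> int:
        """Number of isolates (every listed one) plaque-positive on ``host_id``."""
        return len(self.positives(host_id))

    def dedup_unique(self, host_id: str) -> int:
        """Positive count after collapsing each genome-identity group to one isolate."""
        pos = set(self.positives(host_id))
        n = len(pos)
        for group in self.identity_groups:
            k = len(group & pos)
            if k > 1:
                n -= k - 1
        return n

    def titer_summary(self, host_id: str) -> tuple[float, float]:
        """(min, max) plaque titer over positive cells for ``host_id``."""
        titers = [
            self._cells[(v, host_id)].titer.titer
            for v in self.positives(host_id)
            if self._cells[(v, host_id)].titer is not None
        ]
        if not titers:
            raise ValueError(f"no positive cells with titers for host {host_id!r}")
        return min(titers), max(titers)

    def eop_table(self, test_host_id: str, detection_limit: float | None = None) -> list[EOPRecord]:
        """EOP of every virus on ``test_host_id`` relative to its own isolation host.

        Viruses lacking an own-host reference titer are skipped.
        """
        out: list[EOPRecord] = []
        for v in self.viruses:
            ref_host = v.own_host
            if ref_host is None or ref_host not in self._host_ids:
                continue
            ref_cell = self._cells.get((v.virus_id, ref_host))
            if ref_cell is None or ref_cell.titer is None or ref_cell.titer.titer is None:
                continue
            test_cell = self._cells.get((v.virus_id, test_host_id))
            if test_cell is None or test_cell.call is Call.UNTESTED:
                continue
            test_titer = test_cell.titer.titer if test_cell.titer else None
            out.append(
                compute_eop(
                    test_titer,
                    ref_cell.titer.titer,
                    virus_id=v.virus_id,
                    reference_host_id=ref_host,
                    test_host_id=test_host_id,
                    detection_limit=detection_limit,
                )
            )
        return out

    # -- reports -----------------------------------------------------------

    def report_frame(self) -> pd.DataFrame:
        """Long-format per-cell report: call, titer, EOP vs the virus's own host."""
        eops: dict[tuple[str, str], EOPRecord] = {}
        for host in self.hosts:
            for rec in self.eop_table(host):
                eops[(rec.virus_id, host)] = rec
        rows = []
        for v in self.viruses:
            for h in self.hosts:
                call, obs = self.cell(v.virus_id, h)
                rec = eops.get((v.virus_id, h))
                rows.append(
                    {
                        "virus_id": v.virus_id,
                        "host_id": h,
                        "call": call.value,
                        "titer_pfu_ml": obs.titer if obs else None,
                        "eop": rec.eop_raw if rec else None,
                        "eop_1sf": rec.formatted if rec else None,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        frame = self.report_frame()
        payload = {
            "hosts": self.hosts,
            "viruses": [v.virus_id for v in self.viruses],
            "identity_groups": [sorted(g) for g in self.identity_groups],
            "cells": frame.where(frame.notna(), None).to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def load_lr25_screen() -> HostRangeMatrix:
    """The packaged Haloferax gibbonsii LR2-5 screening table.

    Plaque titers of 25 virus isolates on their own isolation hosts and on
    LR2-5, with the two sequencing-confirmed identity pairs (HCTV-7/HCTV-12 and
    HCTV-6/HCTV-13).
    """
    base = resources.files("halorange.data").joinpath("lr25_host_range")
    with resources.as_file(base.joinpath("titers.csv")) as p:
        titers = pd.read_csv(p, dtype=str)
    with resources.as_file(base.joinpath("viruses.csv")) as p:
        viruses = pd.read_csv(p, dtype=str)
    with resources.as_file(base.joinpath("identity.csv")) as p:
        identity = pd.read_csv(p, dtype=str)
    return HostRangeMatrix.from_tables(titers, viruses, identity)
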