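"""Calibration curves and radiocarbon date tables.

A calibration curve maps calendar age θ (years cal BP, before AD 1950) to the
expected conventional radiocarbon age μc(θ) with a 1σ curve uncertainty σc(θ).
Curves are stored on a knot grid (strictly decreasing cal BP) and evaluated by
piecewise-linear interpolation of both μc and σc; evaluation outside the knot
range is an error rather than an extrapolation, because silent extrapolation
corrupts posteriors.

File dialect (``intcal14c``): the layout shared by the published IntCal20 and
Marine20 distribution files — ``#``-prefixed header lines, then delimited
records whose first three numeric columns are calendar age BP, ¹⁴C age BP and
1σ error.  Extra columns (e.g. Δ¹⁴C) are ignored; comma and whitespace
delimiters are both accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import CurveRangeError, ParseError, ValidationError

MATERIALS = ("terrestrial", "marine")
CURVE_KINDS = ("terrestrial", "marine")


@dataclass
class CalibrationCurve:
    """Gridded calendar-age → ¹⁴C-age mapping with per-knot uncertainty.

    Parameters
    ----------
    name : str
        Label, e.g. ``"intcal20"`` or ``"synthetic-identity"``.
    knots_calbp : array
        Calendar ages of the knots, years cal BP, strictly decreasing.
    knots_c14 : array
        ¹⁴C ages μc at the knots, ¹⁴C yr BP.
    knots_sigma : array
        1σ curve error σc at the knots, ¹⁴C yr; all > 0.
    kind : {"terrestrial", "marine"}
    """

    name: str
    knots_calbp: np.ndarray
    knots_c14: np.ndarray
    knots_sigma: np.ndarray
    kind: str = "terrestrial"

    def __post_init__(self) -> None:
        self.knots_calbp = np.asarray(self.knots_calbp, dtype=float)
        self.knots_c14 = np.asarray(self.knots_c14, dtype=float)
        self.knots_sigma = np.asarray(self.knots_sigma, dtype=float)
        n = self.knots_calbp.size
        if not (self.knots_c14.size == n and self.knots_sigma.size == n):
            raise ValidationError("curve knot arrays must have equal length")
        if n < 2:
            raise ValidationError("a calibration curve needs at least 2 knots")
        d = np.diff(self.knots_calbp)
        if np.all(d > 0):  # normalise ascending input to canonical decreasing
            self.knots_calbp = self.knots_calbp[::-1].copy()
            self.knots_c14 = self.knots_c14[::-1].copy()
            self.knots_sigma = self.knots_sigma[::-1].copy()
        elif not np.all(d < 0):
            raise ValidationError("knots_calbp must be strictly monotone")
        if np.any(self.knots_sigma <= 0):
            raise ValidationError("all curve sigmas must be > 0")
        if self.kind not in CURVE_KINDS:
            raise ValidationError(f"kind must be one of {CURVE_KINDS}")
        # ascending views for np.interp
        self._cal_asc = self.knots_calbp[::-1]
        self._c14_asc = self.knots_c14[::-1]
        self._sig_asc = self.knots_sigma[::-1]

    @property
    def calbp_min(self) -> float:
        return float(self.knots_calbp[-1])

    @property
    def calbp_max(self) -> float:
        return float(self.knots_calbp[0])

    def __call__(self, theta):
        """Interpolate (μc, σc) at calendar age(s) ``theta``.

        Raises :class:`CurveRangeError` if any theta lies outside the knots.
        """
        th = np.asarray(theta, dtype=float)
        if np.any(th < self.calbp_min) or np.any(th > self.calbp_max):
            raise CurveRangeError(
                f"theta outside curve '{self.name}' support "
                f"[{self.calbp_min}, {self.calbp_max}] cal BP"
            )
        mu = np.interp(th, self._cal_asc, self._c14_asc)
        sg = np.interp(th, self._cal_asc, self._sig_asc)
        return mu, sg

    def interp_unchecked(self, theta):
        """Interpolation that returns NaN outside support (MCMC fast path)."""
        th = np.asarray(theta, dtype=float)
        mu = np.interp(th, self._cal_asc, self._c14_asc, left=np.nan, right=np.nan)
        sg = np.interp(th, self._cal_asc, self._sig_asc, left=np.nan, right=np.nan)
        return mu, sg


def interpolate_curve(curve: CalibrationCurve, theta):
    """Piecewise-linear (μc, σc) at ``theta`` cal BP; exact at knots."""
    return curve(theta)


def read_calibration_curve(path, dialect: str = "intcal14c") -> CalibrationCurve:
    """Read a ``.14c``-style curve file.

    Only the first three numeric columns (cal BP, ¹⁴C age, 1σ) are used.
    """
    if dialect != "intcal14c":
        raise ValidationError(f"unknown curve dialect: {dialect!r}")
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                rows.append(tuple(float(v) for v in fields[:3]))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: malformed numeric field"
                ) from None
    if len(rows) < 2:
        raise ValidationError(f"{path}: curve needs at least 2 knots")
    arr = np.asarray(rows, dtype=float)
    name = str(path).rsplit("/", 1)[-1]
    return CalibrationCurve(
        name=name, knots_calbp=arr[:, 0], knots_c14=arr[:, 1], knots_sigma=arr[:, 2]
    )


def write_calibration_curve(curve: CalibrationCurve, path) -> None:
    """Write a curve in the ``intcal14c`` dialect (round-trips with the reader)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {curve.name}\n# cal BP, 14C age BP, 1-sigma error\n")
        for cal, c14, sig in zip(curve.knots_calbp, curve.knots_c14, curve.knots_sigma):
            fh.write(f"{float(cal)!r},{float(c14)!r},{float(sig)!r}\n")


@dataclass
class Determination:
    """One laboratory radiocarbon measurement: x ± σ on the ¹⁴C scale."""

    lab_code: str
    c14_age: float
    c14_sigma: float
    material: str = "terrestrial"
    phase_id: Optional[str] = None
    context_id: Optional[str] = None
    depth_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c14_sigma <= 0:
            raise ValidationError(
                f"{self.lab_code}: c14_sigma must be > 0 (got {self.c14_sigma})"
            )
        if self.material not in MATERIALS:
            raise ValidationError(
                f"{self.lab_code}: material {self.material!r} not in {MATERIALS}"
            )
        if self.depth_m is not None and self.depth_m < 0:
            raise ValidationError(f"{self.lab_code}: depth_m must be >= 0")


@dataclass
class DateTable:
    """Ordered collection of determinations with unique lab codes."""

    rows: List[Determination] = field(default_factory=list)
    provenance: str = "in-memory"

    def __post_init__(self) -> None:
        codes = [r.lab_code for r in self.rows]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate lab_code values: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def get(self, lab_code: str) -> Determination:
        for r in self.rows:
            if r.lab_code == lab_code:
                return r
        raise KeyError(lab_code)

    def subset(self, material: Optional[str] = None,
               lab_codes: Optional[Iterable[str]] = None) -> "DateTable":
        rows = self.rows
        if material is not None:
            rows = [r for r in rows if r.material == material]
        if lab_codes is not None:
            wanted = set(lab_codes)
            rows = [r for r in rows if r.lab_code in wanted]
        return DateTable(rows=list(rows), provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lab_code": r.lab_code,
                    "c14_age": r.c14_age,
                    "c14_sigma": r.c14_sigma,
                    "material": r.material,
                    "phase_id": r.phase_id,
                    "context_id": r.context_id,
                    "depth_m": r.depth_m,
                }
                for r in self.rows
            ]
        )


_REQUIRED_COLS = ("lab_code", "c14_age", "c14_sigma", "material")
_OPTIONAL_COLS = ("phase_id", "context_id", "depth_m")


def read_date_table(path) -> DateTable:
    """Read a delimited date table (comma default, header row required).

    Columns: lab_code, c14_age, c14_sigma, material and optionally phase_id,
    context_id, depth_m.  Missing optional fields are stored as absent.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    rows = []
    for _, rec in df.iterrows():
        kwargs = {
            "lab_code": str(rec["lab_code"]),
            "c14_age": float(rec["c14_age"]),
            "c14_sigma": float(rec["c14_sigma"]),
            "material": str(rec["material"]),
        }
        for col in _OPTIONAL_COLS:
            if col in df.columns and pd.notna(rec[col]):
                kwargs[col] = float(rec[col]) if col == "depth_m" else str(rec[col])
        rows.append(Determination(**kwargs))
    return DateTable(rows=rows, provenance=f"{path} (delimited, header row)")


def write_date_table(table: DateTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def write_summary_table(results: Union[pd.DataFrame, Sequence[Mapping]], path) -> None:
    """Write a summary collection as delimited text with a stable column order.

    Columns are emitted in sorted name order so output bytes do not depend on
    the insertion order of keys in the input records.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(list(results))
    if df.empty:
        raise ValidationError("refusing to write an empty summary table")
    df = df[sorted(df.columns)]
    df.to_csv(path, index=False)
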