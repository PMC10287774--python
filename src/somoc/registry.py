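"""Conversion-equation data model and the built-in equation registry.

A conversion equation predicts soil organic carbon content (OC, % of dry mass)
from loss-on-ignition soil organic matter (SOM, % of dry mass).  Three
functional forms occur in the blue-carbon literature:

    linear      OC = m * SOM + b
    quadratic   OC = a2 * SOM**2 + a1 * SOM + a0
    power       OC = a * SOM**p

All coefficients in this module are stored on the *percent* scale: SOM and OC
both run 0-100, so a linear intercept of 10 means 10% OC at SOM = 0.  The slope
of a linear equation is invariant under the percent/fraction convention, but
the intercept is not (see :func:`convert_intercept_units`), and mixing the two
conventions is a classic source of error when comparing published equations.

The built-in registry bundles every equation in the source compilation: the
general mangrove linear and quadratic fits, equations for six coastal
environmental settings (CES) and two sedimentary settings, seventeen regional
equations, five general blue-carbon ecosystem equations from the earlier
literature, and fourteen previously published regional mangrove equations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Tuple

import yaml

__all__ = [
    "Form",
    "ScopeLevel",
    "CES_CODES",
    "SEDIMENTARY_CODES",
    "ConversionEquation",
    "EquationRegistry",
    "load_builtin_registry",
    "convert_intercept_units",
    "evaluate_equation",
    "is_extrapolated",
]


class Form(str, Enum):
    """Functional form of a conversion equation."""

    LINEAR = "linear"
    QUADRATIC = "quadratic"
    POWER = "power"


class ScopeLevel(str, Enum):
    """Scope at which an equation was derived, from narrowest to broadest."""

    REGION = "region"
    CES = "ces"
    SEDIMENTARY = "sedimentary"
    GENERAL_MANGROVE = "general_mangrove"
    LITERATURE_REGIONAL = "literature_regional"
    LITERATURE_ECOSYSTEM = "literature_ecosystem"


#: Coastal environmental setting codes: terrigenous/carbonate crossed with
#: delta, estuary, lagoon, open coast (no carbonate delta or lagoon class in
#: the built-in set).
CES_CODES = ("TD", "TE", "TL", "TOC", "CE", "COC")

SEDIMENTARY_CODES = ("terrigenous", "carbonate")

# Coefficient slots expected per functional form.  Optional slots may be
# absent when the source did not publish them (e.g. "n/a" intercepts).
_FORM_SLOTS = {
    Form.LINEAR: (("m",), ("b",)),
    Form.QUADRATIC: (("a2", "a1"), ("a0",)),
    Form.POWER: (("a", "p"), ()),
}


@dataclass(frozen=True)
class ConversionEquation:
    """A published or fitted SOM-to-OC conversion equation.

    Parameters
    ----------
    id : str
        Unique short identifier.
    scope_level : ScopeLevel
        Scope at which the equation applies.
    scope_key : str
        Region name, CES code, or sedimentary code; empty for general scopes.
    form : Form
        Functional form.
    coefficients : dict
        Coefficients on the percent scale, keyed per form
        (linear: ``m``/``b``; quadratic: ``a2``/``a1``/``a0``; power:
        ``a``/``p``).  Optional slots (intercepts) may be omitted when the
        source reports none; such equations evaluate as pure slope/curvature.
    coefficient_se : dict, optional
        One-standard-error uncertainties, same keys as ``coefficients``.
    r_squared : float, optional
        Coefficient of determination, 0-1.
    n : int, optional
        Number of samples behind the fit.
    som_validity_range : (float, float), optional
        SOM range (%) of the calibration data; predictions outside it are
        extrapolations.
    provenance : str
        Citation key for the source.
    """

    id: str
    scope_level: ScopeLevel
    scope_key: str
    form: Form
    coefficients: dict
    coefficient_se: Optional[dict] = None
    r_squared: Optional[float] = None
    n: Optional[int] = None
    som_validity_range: Optional[Tuple[float, float]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "scope_level", ScopeLevel(self.scope_level))
        object.__setattr__(self, "form", Form(self.form))
        required, optional = _FORM_SLOTS[self.form]
        allowed = set(required) | set(optional)
        got = set(self.coefficients)
        if not set(required) <= got:
            missing = set(required) - got
            raise ValueError(f"{self.id}: missing coefficient(s) {sorted(missing)}")
        if not got <= allowed:
            extra = got - allowed
            raise ValueError(
                f"{self.id}: coefficient(s) {sorted(extra)} not valid for "
                f"form {self.form.value!r}"
            )
        if self.coefficient_se is not None and not set(self.coefficient_se) <= allowed:
            raise ValueError(f"{self.id}: SE keys must match coefficient slots")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"{self.id}: r_squared must lie in [0, 1]")
        if self.som_validity_range is not None:
            lo, hi = self.som_validity_range
            if not lo <= hi:
                raise ValueError(f"{self.id}: invalid som_validity_range")
            object.__setattr__(self, "som_validity_range", (float(lo), float(hi)))

    @property
    def slope(self) -> Optional[float]:
        """Linear slope m (= OC:SOM when the intercept is dropped)."""
        return self.coefficients.get("m") if self.form is Form.LINEAR else None

    @property
    def intercept(self) -> Optional[float]:
        if self.form is Form.LINEAR:
            return self.coefficients.get("b")
        if self.form is Form.QUADRATIC:
            return self.coefficients.get("a0")
        return None


def convert_intercept_units(b: float, from_convention: str, to_convention: str) -> float:
    """Convert a linear intercept between the percent and fraction conventions.

    With variables on the percent scale an intercept of 10 means 10% OC;
    on the fraction scale the same physical intercept is written 0.10.
    The slope is unaffected by the convention and is never converted.
    """
    conventions = {"percent", "fraction"}
    if from_convention not in conventions or to_convention not in conventions:
        raise ValueError("conventions must be 'percent' or 'fraction'")
    if from_convention == to_convention:
        return b
    if from_convention == "percent":
        return b / 100.0
    return b * 100.0


def evaluate_equation(eq: ConversionEquation, som: float) -> float:
    """Evaluate a conversion equation at a SOM value (percent scale).

    Returns the raw model value; it is *not* clamped at zero — several
    published equations have negative intercepts and predict negative OC at
    low SOM, and clamping is the estimator's concern (see
    :mod:`somoc.estimate`).
    """
    c = eq.coefficients
    if eq.form is Form.LINEAR:
        return c["m"] * som + c.get("b", 0.0)
    if eq.form is Form.QUADRATIC:
        return c["a2"] * som**2 + c["a1"] * som + c.get("a0", 0.0)
    if eq.form is Form.POWER:
        return c["a"] * som ** c["p"]
    raise ValueError(f"unknown equation form: {eq.form!r}")


def is_extrapolated(eq: ConversionEquation, som: float) -> bool:
    """Whether ``som`` lies outside the equation's calibration SOM range."""
    if eq.som_validity_range is None:
        return False
    lo, hi = eq.som_validity_range
    return som < lo or som > hi


# ---------------------------------------------------------------------------
# Registry container

_CSV_COLUMNS = [
    "id", "scope_level", "scope_key", "form",
    "m", "b", "a2", "a1", "a0", "a", "p",
    "se_m", "se_b", "se_a2", "se_a1", "se_a0", "se_a", "se_p",
    "r_squared", "n", "som_min", "som_max", "provenance",
]


class EquationRegistry:
    """Collection of conversion equations with scope-based lookup."""

    def __init__(self, equations: Iterable[ConversionEquation] = ()) -> None:
        self._by_id: dict = {}
        for eq in equations:
            self.add(eq)

    def add(self, eq: ConversionEquation) -> None:
        if eq.id in self._by_id:
            raise ValueError(f"duplicate equation id {eq.id!r}")
        self._by_id[eq.id] = eq

    def get(self, eq_id: str) -> ConversionEquation:
        return self._by_id[eq_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[ConversionEquation]:
        return iter(self._by_id.values())

    def __contains__(self, eq_id: str) -> bool:
        return eq_id in self._by_id

    def lookup(
        self,
        scope_level: Optional[str] = None,
        scope_key: Optional[str] = None,
    ) -> list:
        """All equations matching a scope level and/or scope key."""
        level = ScopeLevel(scope_level) if scope_level is not None else None
        out = []
        for eq in self._by_id.values():
            if level is not None and eq.scope_level is not level:
                continue
            if scope_key is not None and eq.scope_key != scope_key:
                continue
            out.append(eq)
        return out

    def lookup_one(self, scope_level: str, scope_key: str) -> ConversionEquation:
        hits = self.lookup(scope_level, scope_key)
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one equation at ({scope_level}, {scope_key!r}); "
                f"found {len(hits)}"
            )
        return hits[0]

    # -- self-checks -------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants of a registry holding the built-ins."""
        for code in CES_CODES:
            if len(self.lookup(ScopeLevel.CES, code)) != 1:
                raise AssertionError(f"CES code {code} must have exactly one equation")
        for code in SEDIMENTARY_CODES:
            hits = self.lookup(ScopeLevel.SEDIMENTARY, code)
            if len(hits) != 1 or hits[0].form is not Form.QUADRATIC:
                raise AssertionError(
                    f"sedimentary code {code} must have exactly one quadratic"
                )
        gen = self.lookup(ScopeLevel.GENERAL_MANGROVE)
        forms = sorted(eq.form.value for eq in gen)
        if forms != ["linear", "quadratic"]:
            raise AssertionError("general scope must hold one linear and one quadratic")
        for eq in self:
            if eq.form is Form.LINEAR and not 0.0 < eq.coefficients["m"] < 1.0:
                raise AssertionError(f"{eq.id}: linear slope must lie in (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write one equation per row as delimited text (exact float repr)."""
        rows = [self._to_row(eq) for eq in self]
        if hasattr(path_or_buf, "write"):
            writer = csv.DictWriter(path_or_buf, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
        else:
            with open(path_or_buf, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
                writer.writeheader()
                writer.writerows(rows)

    @classmethod
    def from_csv(cls, path_or_buf) -> "EquationRegistry":
        if hasattr(path_or_buf, "read"):
            reader = csv.DictReader(path_or_buf)
            rows = list(reader)
        else:
            with open(path_or_buf, newline="") as fh:
                rows = list(csv.DictReader(fh))
        return cls(cls._from_row(r) for r in rows)

    def to_yaml(self, path_or_buf) -> None:
        """Write the registry as a structured config file."""
        payload = {"equations": [self._to_mapping(eq) for eq in self]}
        text = yaml.safe_dump(payload, sort_keys=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, path_or_buf) -> "EquationRegistry":
        if hasattr(path_or_buf, "read"):
            payload = yaml.safe_load(path_or_buf)
        else:
            with open(path_or_buf) as fh:
                payload = yaml.safe_load(fh)
        return cls(cls._from_mapping(m) for m in payload["equations"])

    # -- row/mapping helpers ----------------------------------------------

    @staticmethod
    def _to_row(eq: ConversionEquation) -> dict:
        row = {k: "" for k in _CSV_COLUMNS}
        row.update(
            id=eq.id,
            scope_level=eq.scope_level.value,
            scope_key=eq.scope_key,
            form=eq.form.value,
            provenance=eq.provenance,
        )
        for key, val in eq.coefficients.items():
            row[key] = repr(float(val))
        for key, val in (eq.coefficient_se or {}).items():
            row[f"se_{key}"] = repr(float(val))
        if eq.r_squared is not None:
            row["r_squared"] = repr(float(eq.r_squared))
        if eq.n is not None:
            row["n"] = str(int(eq.n))
        if eq.som_validity_range is not None:
            row["som_min"] = repr(float(eq.som_validity_range[0]))
            row["som_max"] = repr(float(eq.som_validity_range[1]))
        return row

    @staticmethod
    def _from_row(row: dict) -> ConversionEquation:
        coeffs = {}
        ses = {}
        for key in ("m", "b", "a2", "a1", "a0", "a", "p"):
            if row.get(key, "") != "":
                coeffs[key] = float(row[key])
            if row.get(f"se_{key}", "") != "":
                ses[f"{key}"] = float(row[f"se_{key}"])
        rng = None
        if row.get("som_min", "") != "":
            rng = (float(row["som_min"]), float(row["som_max"]))
        return ConversionEquation(
            id=row["id"],
            scope_level=row["scope_level"],
            scope_key=row["scope_key"],
            form=row["form"],
            coefficients=coeffs,
            coefficient_se=ses or None,
            r_squared=float(row["r_squared"]) if row.get("r_squared", "") != "" else None,
            n=int(row["n"]) if row.get("n", "") != "" else None,
            som_validity_range=rng,
            provenance=row.get("provenance", ""),
        )

    @staticmethod
    def _to_mapping(eq: ConversionEquation) -> dict:
        m = {
            "id": eq.id,
            "scope_level": eq.scope_level.value,
            "scope_key": eq.scope_key,
            "form": eq.form.value,
            "coefficients": {k: float(v) for k, v in eq.coefficients.items()},
        }
        if eq.coefficient_se is not None:
            m["coefficient_se"] = {k: float(v) for k, v in eq.coefficient_se.items()}
        if eq.r_squared is not None:
            m["r_squared"] = float(eq.r_squared)
        if eq.n is not None:
            m["n"] = int(eq.n)
        if eq.som_validity_range is not None:
            m["som_validity_range"] = [float(x) for x in eq.som_validity_range]
        if eq.provenance:
            m["provenance"] = eq.provenance
        return m

    @staticmethod
    def _from_mapping(m: dict) -> ConversionEquation:
        rng = m.get("som_validity_range")
        return ConversionEquation(
            id=m["id"],
            scope_level=m["scope_level"],
            scope_key=m["scope_key"],
            form=m["form"],
            coefficients=dict(m["coefficients"]),
            coefficient_se=dict(m["coefficient_se"]) if "coefficient_se" in m else None,
            r_squared=m.get("r_squared"),
            n=m.get("n"),
            som_validity_range=tuple(rng) if rng is not None else None,
            provenance=m.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# Built-in equations.
#
# Every coefficient below is on the percent scale (SOM, OC in 0-100).
# Intercepts the source reported as "n/a" are absent, and such equations
# evaluate as pure slope.  SEs of 0.000 are stored as printed (rounded).

def _lin(id, level, key, m, se_m, b=None, se_b=None, r2=None, n=None, rng=None, prov=""):
    coeffs = {"m": m}
    ses = {}
    if se_m is not None:
        ses["m"] = se_m
    if b is not None:
        coeffs["b"] = b
        if se_b is not None:
            ses["b"] = se_b
    return ConversionEquation(
        id=id, scope_level=level, scope_key=key, form=Form.LINEAR,
        coefficients=coeffs, coefficient_se=ses or None,
        r_squared=r2, n=n, som_validity_range=rng, provenance=prov,
    )


# Seventeen regional equations, linear form, with CES membership recorded in
# REGION_CES.  (region, slope, se, intercept, se, R^2, n)
_REGIONAL_ROWS = [
    ("St. Augustine",              "TL",  0.283, 0.012, -0.3,  0.1, 0.96,  29),
    ("Apalachicola Bay",           "TL",  0.392, 0.016, -0.1,  0.3, 0.96,  27),
    ("Waccasassa Bay",             "TOC", 0.360, 0.028, -2.8,  0.9, 0.87,  28),
    ("Merritt Island",             "TL",  0.460, 0.009, -0.3,  0.3, 0.98,  50),
    ("Tampa Bay",                  "CE",  0.427, 0.016, -0.2,  0.6, 0.9,   80),
    ("Charlotte Harbor",           "CE",  0.465, 0.015,  1.2,  0.7, 0.96,  43),
    ("Ten Thousand Islands",       "COC", 0.442, 0.019,  0.9,  1.0, 0.75, 183),
    ("Biscayne Bay",               "COC", 0.439, 0.032,  1.5,  1.5, 0.88,  29),
    ("Southwest Everglades",       "CE",  0.515, 0.006, -2.2,  0.4, 0.93, 543),
    ("Southeast Everglades",       "CE",  0.519, 0.020, -4.5,  1.1, 0.95,  36),
    ("Lower Keys",                 "COC", 0.521, 0.033, -1.9,  2.3, 0.92,  23),
    ("Laguna Gandoca",             "TL",  0.687, 0.036, -15.5, 2.3, 0.95,  21),
    ("Marapanim",                  "TD",  0.240, 0.038,  0.1,  0.5, 0.80,  12),
    ("Caravelas",                  "TD",  0.321, 0.022, -2.1,  0.5, 0.86,  36),
    ("Garapua",                    "TOC", 0.369, 0.027,  0.1,  0.5, 0.85,  36),
    ("Ratones, Itapoa, & Guaratuba", "TE", 0.249, 0.034, 0.0,  0.4, 0.63,  34),
    ("Sao Paulo State",            "TL",  0.355, 0.026, -0.7,  0.5, 0.85,  36),
]

#: CES membership of each built-in study region.
REGION_CES = {row[0]: row[1] for row in _REGIONAL_ROWS}

# CES-level equations: (code, slope, se, intercept, se, R^2, n)
_CES_ROWS = [
    ("CE",  0.506, 0.005, -1.7, 0.3, 0.94, 702),
    ("COC", 0.470, 0.014, -0.6, 0.7, 0.82, 235),
    ("TD",  0.287, 0.019, -1.2, 0.4, 0.84,  48),
    ("TE",  0.250, 0.033,  0.9, 3.7, 0.64,  34),
    ("TL",  0.472, 0.007, -1.7, 0.2, 0.97, 163),
    ("TOC", 0.281, 0.021,  0.7, 0.5, 0.75,  64),
]

# Previously published regional mangrove equations:
# (key, CES or None, n or None, m, b or None, R^2, SOM range or None)
_LITERATURE_REGIONAL_ROWS = [
    ("Mui Ca Mau, Vietnam",      "TD",  225, 0.23,  0.2,  0.56, (3, 20)),
    ("Chek Jawa, Singapore",     "TE",   40, 0.24,  1.2,  0.46, (0, 30)),
    ("Hau Loc, Vietnam",         "TOC", None, 0.25, -2.7, 0.72, (2, 11)),
    ("Ceara State, Brazil",      "TE",   60, 0.27,  None, 0.82, (5, 30)),
    ("Can Gio, Vietnam",         "TD",  316, 0.35, -1.3,  0.80, (5, 20)),
    ("Sao Paulo State, Brazil",  "TL",   36, 0.35, -0.69, 0.84, (5, 27)),
    ("Matang, Malaysia",         None,  103, 0.37, -0.1,  0.61, (20, 55)),
    ("Dong Rui, Vietnam",        "TOC",  30, 0.41,  None, 0.79, (3, 17)),
    ("Tampa Bay, FL, USA",       "CE",   57, 0.42,  None, 0.95, (2, 69)),
    ("Republic of Palau",        "COC",  78, 0.42,  2.9,  0.59, (15, 52)),
    ("Gazi Bay & Vanga, Kenya",  None,   70, 0.43,  0.2,  0.64, None),
    ("Chonburi, Thailand",       "TE",   29, 0.50,  0.10, 0.25, (6, 17)),
    ("Jervis Bay, Australia",    "TE",   32, 0.51,  0.2,  0.95, (0, 16)),
    ("Muisne Island, Ecuador",   None,  None, 0.87, -5.8, 0.89, (0, 35)),
]

_LITREG_PROV = [
    "tue2014", "phang2015", "vanhieu2017", "nobrega2019", "dung2016",
    "rovai2021", "adame2018", "nguyen2020", "radabaugh2018", "kauffman2012",
    "gress2017", "chaikaew2017", "owers2020", "delvecchia2014",
]


def _slugify(name: str) -> str:
    out = []
    for ch in name.lower():
        if ch.isalnum():
            out.append(ch)
        elif out and out[-1] != "_":
            out.append("_")
    return "".join(out).strip("_")


def load_builtin_registry() -> EquationRegistry:
    """Build the registry of all built-in published conversion equations."""
    reg = EquationRegistry()

    # General mangrove equations from the primary 17-region dataset.
    reg.add(_lin(
        "gen_linear", ScopeLevel.GENERAL_MANGROVE, "",
        0.511, 0.003, -2.497, 0.174, r2=0.95, n=1246, rng=(1.1, 87.1),
        prov="this_study",
    ))
    reg.add(ConversionEquation(
        id="gen_quadratic", scope_level=ScopeLevel.GENERAL_MANGROVE, scope_key="",
        form=Form.QUADRATIC,
        coefficients={"a2": 0.001, "a1": 0.380, "a0": -0.425},
        coefficient_se={"a2": 0.000, "a1": 0.013, "a0": 0.262},
        r_squared=0.95, n=1246, som_validity_range=(1.1, 87.1),
        provenance="this_study",
    ))

    for region, _ces, m, se_m, b, se_b, r2, n in _REGIONAL_ROWS:
        reg.add(_lin(
            f"reg_{_slugify(region)}", ScopeLevel.REGION, region,
            m, se_m, b, se_b, r2=r2, n=n, prov="this_study",
        ))

    for code, m, se_m, b, se_b, r2, n in _CES_ROWS:
        reg.add(_lin(
            f"ces_{code.lower()}", ScopeLevel.CES, code,
            m, se_m, b, se_b, r2=r2, n=n, prov="this_study",
        ))

    # Sedimentary-setting quadratics.
    reg.add(ConversionEquation(
        id="sed_terrigenous", scope_level=ScopeLevel.SEDIMENTARY,
        scope_key="terrigenous", form=Form.QUADRATIC,
        coefficients={"a2": 0.004, "a1": 0.217, "a0": 0.3},
        coefficient_se={"a2": 0.000, "a1": 0.022, "a0": 0.3},
        r_squared=0.94, n=309, provenance="this_study",
    ))
    reg.add(ConversionEquation(
        id="sed_carbonate", scope_level=ScopeLevel.SEDIMENTARY,
        scope_key="carbonate", form=Form.QUADRATIC,
        coefficients={"a2": 0.002, "a1": 0.326, "a0": 1.8},
        coefficient_se={"a2": 0.000, "a1": 0.019, "a0": 0.4},
        r_squared=0.93, n=937, provenance="this_study",
    ))

    # General blue-carbon ecosystem equations from the earlier literature.
    # The zero-intercept saltmarsh quadratic is stored with its printed
    # coefficients acting on the percent scale, the reading consistent with
    # its published OC:SOM range of 0.41-0.65 over SOM 0-73%.
    reg.add(ConversionEquation(
        id="lit_saltmarsh_quadratic", scope_level=ScopeLevel.LITERATURE_ECOSYSTEM,
        scope_key="saltmarsh", form=Form.QUADRATIC,
        coefficients={"a2": 0.0025, "a1": 0.40},
        coefficient_se={"a2": 0.0003, "a1": 0.01},
        r_squared=0.99, n=250, som_validity_range=(0, 73),
        provenance="craft1991",
    ))
    reg.add(_lin(
        "lit_saltmarsh_linear", ScopeLevel.LITERATURE_ECOSYSTEM, "saltmarsh",
        0.52, 0.006, -1.17, 0.12, r2=0.99, n=344, rng=(0, 70),
        prov="ouyang2020",
    ))
    reg.add(_lin(
        "lit_seagrass_low_som", ScopeLevel.LITERATURE_ECOSYSTEM, "seagrass",
        0.40, None, -0.21, None, r2=0.87, n=1667, rng=(0, 20),
        prov="fourqurean2012",
    ))
    reg.add(_lin(
        "lit_seagrass_high_som", ScopeLevel.LITERATURE_ECOSYSTEM, "seagrass",
        0.43, None, -0.33, None, r2=0.96, n=1748, rng=(0, 100),
        prov="fourqurean2012",
    ))
    reg.add(ConversionEquation(
        id="lit_mangrove_power", scope_level=ScopeLevel.LITERATURE_ECOSYSTEM,
        scope_key="mangrove", form=Form.POWER,
        coefficients={"a": 0.21, "p": 1.12},
        coefficient_se={"a": 0.01, "p": 0.02},
        r_squared=0.86, n=1534, som_validity_range=(0, 80),
        provenance="ouyang2020",
    ))

    # Previously published regional mangrove equations.  The Palau intercept
    # (2.9) is stored on the percent scale per the standardization used for
    # every built-in; see its provenance key.
    for (key, _ces, n, m, b, r2, rng), prov in zip(
        _LITERATURE_REGIONAL_ROWS, _LITREG_PROV
    ):
        reg.add(_lin(
            f"litreg_{_slugify(key)}", ScopeLevel.LITERATURE_REGIONAL, key,
            m, None, b, None, r2=r2, n=n, rng=rng, prov=prov,
        ))

    reg.validate()
    return reg
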