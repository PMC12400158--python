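"""Rule-based annotation of MS2 spectra of phenylpropanoids and flavonoids.

The module encodes the diagnostic fragmentation chemistry of the two compound
families that dominate UV-active herbal extracts such as mugwort leaf:

* **Caffeoylquinic acids (CQAs)** - esters of quinic acid with 1-3 caffeic
  acid units.  In negative mode they shed caffeoyl moieties (C9H6O3,
  162.03169 Da) one by one down to the quinate anion at m/z 191.0561, with
  support ions from the caffeate side (179.0350, 135.0452) and dehydrated
  quinate (173.0455).  Positional isomers share all of these ions and are
  told apart only by the *relative abundances* of the base peak and of the
  m/z 179 / 173 ions.
* **Flavonoids** - aglycones fragment through the retro Diels-Alder (RDA)
  cleavage of the C ring, O-glycosides first lose the intact sugar and then
  behave like their aglycone, and C-glycosides lose 60/90/120 Da pieces of
  the sugar ring while their aglycone does not undergo RDA at all.  The RDA
  and ring-cleavage evidence exists only in negative mode, which is why
  negative-mode spectra score strictly higher.

All m/z values are computed from summed IUPAC monoisotopic atomic masses;
observed instrument values are matched against them within a ppm tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC",
    "PROTON",
    "LOSS",
    "Spectrum",
    "FragmentIon",
    "FragmentRule",
    "CompoundHypothesis",
    "COMPOUND_LIBRARY",
    "parse_formula",
    "monoisotopic_mass",
    "theoretical_mz",
    "ppm_error",
    "classify_cqa",
    "discriminate_cqa_isomer",
    "classify_flavonoid",
    "annotate",
]

#: Monoisotopic atomic masses (Da).
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of a proton (Da); [M-H]- = M - PROTON, [M+H]+ = M + PROTON.
PROTON = 1.007276

DEFAULT_TOL_PPM = 10.0

#: Window for resolving nominal-mass anchors (m/z "179", "173", "191") to the
#: exact diagnostic ion before abundance comparison.
NOMINAL_WINDOW_DA = 0.01

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class AnnotationError(ValueError):
    """Raised for spectra or formulas the annotator cannot process."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition such as ``"C9H6O3"`` into counts.

    Only C, H, N, O, S are accepted; an empty string is the empty
    composition (mass zero).
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise AnnotationError(f"cannot parse formula {formula!r}")
        if not match.group(0):
            break
        element, mult = match.group(1), match.group(2)
        if element not in MONOISOTOPIC:
            raise AnnotationError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(mult) if mult else 1)
        pos = match.end()
    if pos != len(formula):
        raise AnnotationError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental composition."""
    return sum(MONOISOTOPIC[el] * n for el, n in parse_formula(formula).items())


#: Neutral-loss and building-block masses used by the rule library.
LOSS: dict[str, float] = {
    "caffeoyl": monoisotopic_mass("C9H6O3"),        # 162.03169
    "water": monoisotopic_mass("H2O"),              # 18.01056
    "CO2": monoisotopic_mass("CO2"),                # 43.98983
    "CO": monoisotopic_mass("CO"),                  # 27.99491
    "ring_60": monoisotopic_mass("C2H4O2"),         # 60.02113
    "ring_90": monoisotopic_mass("C3H6O3"),         # 90.03169
    "ring_120": monoisotopic_mass("C4H8O4"),        # 120.04226
    "hexosyl": monoisotopic_mass("C6H10O5"),        # 162.05282
    "deoxyhexosyl": monoisotopic_mass("C6H10O4"),   # 146.05791
    "rutinosyl": monoisotopic_mass("C12H20O9"),     # 308.11073
}


def theoretical_mz(formula_or_mass: str | float, polarity: str) -> float:
    """m/z of [M-H]- or [M+H]+ for a neutral formula or neutral mass."""
    mass = (
        monoisotopic_mass(formula_or_mass)
        if isinstance(formula_or_mass, str)
        else float(formula_or_mass)
    )
    if polarity == "negative":
        if mass <= PROTON:
            raise AnnotationError("neutral mass below proton mass in negative mode")
        return mass - PROTON
    if polarity == "positive":
        return mass + PROTON
    raise AnnotationError(f"polarity must be 'negative' or 'positive', got {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise AnnotationError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Spectrum container
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A centroided MS2 spectrum with abundances in percent of base peak."""

    precursor_mz: float
    polarity: str
    peaks: list[tuple[float, float]]
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise AnnotationError(f"bad polarity {self.polarity!r}")
        if self.precursor_mz <= 0:
            raise AnnotationError("precursor m/z must be positive")
        if self.peaks:
            n_base = sum(1 for _, ab in self.peaks if abs(ab - 100.0) < 1e-9)
            if n_base != 1:
                raise AnnotationError("spectrum must have exactly one 100% base peak")
            for mz, ab in self.peaks:
                if mz <= 0 or not (0 < ab <= 100.0):
                    raise AnnotationError("peak m/z must be > 0 and abundance in (0, 100]")

    @property
    def base_peak_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]

    def abundance_at(self, mz: float, window: float = NOMINAL_WINDOW_DA) -> float:
        """Summed relative abundance within ``window`` Da of ``mz`` (0 if absent)."""
        return sum(ab for m, ab in self.peaks if abs(m - mz) <= window)

    def find_ion(self, mz_theor: float, tol_ppm: float) -> tuple[float, float] | None:
        """Most abundant peak within ``tol_ppm`` of ``mz_theor``, or None."""
        tol = abs(mz_theor) * tol_ppm * 1e-6
        hits = [(m, ab) for m, ab in self.peaks if abs(m - mz_theor) <= tol]
        return max(hits, key=lambda p: p[1]) if hits else None


# ---------------------------------------------------------------------------
# Rule library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentIon:
    """A diagnostic ion: label, theoretical m/z and reference abundance (%)."""

    label: str
    mz: float
    abundance: float


@dataclass
class FragmentRule:
    """Reference fragmentation behaviour of one library compound."""

    compound_id: str
    compound_class: str  # monoCQA | diCQA | triCQA | phenylpropanoid acid |
    #                      flavone aglycone | flavonol O-glycoside | flavonoid C-glycoside
    formula: str
    isomer: str | None = None
    fragments: dict[str, list[FragmentIon]] = field(default_factory=dict)

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def precursor_mz(self, polarity: str) -> float:
        return theoretical_mz(self.formula, polarity)

    def reference_spectrum(self, polarity: str) -> list[FragmentIon]:
        ions = self.fragments.get(polarity)
        if ions is None:
            raise AnnotationError(
                f"no {polarity}-mode reference inventory for {self.compound_id!r}"
            )
        return ions


@dataclass
class CompoundHypothesis:
    """A scored class/isomer assignment for one spectrum."""

    compound_class: str
    isomer: str | None = None
    matched: list[tuple[str, float, float, float]] = field(default_factory=list)
    # (label, expected mz, observed mz, ppm)
    score: float = 0.0
    note: str = ""


def _ion(label: str, mz: float, abundance: float) -> FragmentIon:
    return FragmentIon(label, mz, abundance)


def _build_library() -> list[FragmentRule]:
    """Construct the compound library from mass arithmetic.

    Reference relative abundances follow the measured isomer discriminators
    where these are known (52.54 / 1.09 % for m/z 179 among mono-CQAs;
    44.28 / 29.35 / 1.26 % for m/z 173 among di-CQAs); the remaining
    abundances are representative values inside the rule windows.
    """
    quinate = theoretical_mz("C7H12O6", "negative")            # 191.05611
    quinate_h2o = quinate - LOSS["water"]                      # 173.04555
    caffeate = theoretical_mz("C9H8O4", "negative")            # 179.03498
    caffeate_co2 = caffeate - LOSS["CO2"]                      # 135.04515

    def cqa_ions(n_caffeoyl: int, prec: float, base_label: str, ab: dict[str, float]):
        """Negative-mode inventory for a CQA of caffeoylation degree n."""
        ions = []
        running = prec
        for k in range(1, n_caffeoyl + 1):
            running -= LOSS["caffeoyl"]
            label = f"[M-{k}caffeoyl-H]-" if k < n_caffeoyl else "quinate"
            default = 100.0 if label == base_label else 40.0
            ions.append(_ion(label, running, ab.get(label, default)))
        ions.append(_ion("quinate-H2O", quinate_h2o, ab.get("quinate-H2O", 25.0)))
        ions.append(_ion("caffeate", caffeate, ab.get("caffeate", 30.0)))
        ions.append(_ion("caffeate-CO2", caffeate_co2, ab.get("caffeate-CO2", 12.0)))
        ions.append(_ion("[M-H]-", prec, ab.get("[M-H]-", 8.0)))
        return ions

    mono = monoisotopic_mass("C16H18O9")
    di = monoisotopic_mass("C25H24O12")
    tri = monoisotopic_mass("C34H30O15")

    library: list[FragmentRule] = []

    mono_prec = mono - PROTON
    for isomer, ab179, ab173, base in (
        ("neochlorogenic acid", 52.54, 30.0, "quinate"),
        ("chlorogenic acid", 1.09, 5.0, "quinate"),
        ("cryptochlorogenic acid", 40.0, 100.0, "quinate-H2O"),
    ):
        ab = {"caffeate": ab179, "quinate-H2O": ab173}
        if base == "quinate-H2O":
            ab["quinate"] = 60.0
        library.append(
            FragmentRule(
                compound_id=isomer,
                compound_class="monoCQA",
                formula="C16H18O9",
                isomer=isomer,
                fragments={"negative": cqa_ions(1, mono_prec, base, ab)},
            )
        )

    di_prec = di - PROTON
    m_caffeoyl = di_prec - LOSS["caffeoyl"]
    for isomer, ab173, base in (
        ("isochlorogenic acid B", 44.28, "[M-1caffeoyl-H]-"),
        ("isochlorogenic acid C", 29.35, "[M-1caffeoyl-H]-"),
        ("isochlorogenic acid A", 1.26, "[M-1caffeoyl-H]-"),
        ("1,5-O-dicaffeoylquinic acid", 10.0, "quinate"),
    ):
        ab = {"quinate-H2O": ab173, "caffeate": 30.0, "quinate": 45.0}
        if base == "quinate":
            ab["quinate"] = 100.0
            ab["[M-1caffeoyl-H]-"] = 70.0
        ions = cqa_ions(2, di_prec, base, ab)
        ions.append(_ion("[M-caffeoyl-H2O-H]-", m_caffeoyl - LOSS["water"], 15.0))
        library.append(
            FragmentRule(
                compound_id=isomer,
                compound_class="diCQA",
                formula="C25H24O12",
                isomer=isomer,
                fragments={"negative": ions},
            )
        )

    library.append(
        FragmentRule(
            compound_id="3,4,5-tricaffeoylquinic acid",
            compound_class="triCQA",
            formula="C34H30O15",
            isomer="3,4,5-tricaffeoylquinic acid",
            fragments={
                "negative": cqa_ions(
                    3,
                    tri - PROTON,
                    "quinate",
                    {"[M-1caffeoyl-H]-": 50.0, "[M-2caffeoyl-H]-": 80.0,
                     "quinate-H2O": 30.0, "caffeate": 40.0},
                )
            },
        )
    )

    library.append(
        FragmentRule(
            compound_id="caffeic acid",
            compound_class="phenylpropanoid acid",
            formula="C9H8O4",
            fragments={
                "negative": [
                    _ion("caffeate-CO2", caffeate_co2, 100.0),
                    _ion("[M-H]-", caffeate, 55.0),
                ]
            },
        )
    )

    # Flavonoid RDA inventories are stored per aglycone class, not derived
    # from substitution patterns.
    rda_luteolin_like = [
        ("1,3A-", theoretical_mz("C7H4O4", "negative"), 45.0),   # 151.0037
        ("0,2A-", theoretical_mz("C8H6O3", "negative"), 30.0),   # 149.0244
        ("0,4A-", theoretical_mz("C6H4O2", "negative"), 20.0),   # 107.0139
    ]
    rda_quercetin_like = [
        ("1,2A-", theoretical_mz("C8H4O5", "negative"), 25.0),   # 178.9986
        ("1,2A--CO", theoretical_mz("C8H4O5", "negative") - LOSS["CO"], 20.0),
    ]

    for name, formula in (("luteolin", "C15H10O6"), ("apigenin", "C15H10O5")):
        prec_neg = theoretical_mz(formula, "negative")
        library.append(
            FragmentRule(
                compound_id=name,
                compound_class="flavone aglycone",
                formula=formula,
                fragments={
                    "negative": [_ion("[M-H]-", prec_neg, 100.0)]
                    + [_ion(lbl, mz, ab) for lbl, mz, ab in rda_luteolin_like],
                    "positive": [
                        _ion("[M+H]+", theoretical_mz(formula, "positive"), 100.0),
                        _ion("1,3A+", monoisotopic_mass("C7H4O4") + PROTON, 25.0),
                    ],
                },
            )
        )

    quercetin_neg = theoretical_mz("C15H10O7", "negative")       # 301.0354
    quercetin_pos = theoretical_mz("C15H10O7", "positive")       # 303.0499
    for name, formula, sugar in (
        ("rutin", "C27H30O16", "rutinosyl"),
        ("isoquercetin", "C21H20O12", "hexosyl"),
    ):
        prec_neg = theoretical_mz(formula, "negative")
        ions_neg = [
            _ion("aglycone", quercetin_neg, 100.0),
            _ion("aglycone radical", quercetin_neg - MONOISOTOPIC["H"], 60.0),
            _ion("[M-H]-", prec_neg, 30.0),
        ] + [_ion(lbl, mz, ab) for lbl, mz, ab in rda_quercetin_like]
        library.append(
            FragmentRule(
                compound_id=name,
                compound_class="flavonol O-glycoside",
                formula=formula,
                fragments={
                    "negative": ions_neg,
                    "positive": [
                        _ion("aglycone+", quercetin_pos, 100.0),
                        _ion("[M+H]+", theoretical_mz(formula, "positive"), 40.0),
                    ],
                },
            )
        )

    schaft = theoretical_mz("C26H28O14", "negative")             # 563.1406
    library.append(
        FragmentRule(
            compound_id="schaftoside",
            compound_class="flavonoid C-glycoside",
            formula="C26H28O14",
            fragments={
                "negative": [
                    _ion("[M-H]-", schaft, 100.0),
                    _ion("[M-H-90]-", schaft - LOSS["ring_90"], 35.0),
                    _ion("[M-H-120]-", schaft - LOSS["ring_120"], 55.0),
                    _ion("[M-H-120-60]-", schaft - LOSS["ring_120"] - LOSS["ring_60"], 20.0),
                    _ion("[M-H-120-90]-", schaft - LOSS["ring_120"] - LOSS["ring_90"], 25.0),
                    _ion(
                        "[M-H-120-90-CO]-",
                        schaft - LOSS["ring_120"] - LOSS["ring_90"] - LOSS["CO"],
                        10.0,
                    ),
                ],
                "positive": [
                    _ion("[M+H]+", theoretical_mz("C26H28O14", "positive"), 100.0)
                ],
            },
        )
    )

    return library


COMPOUND_LIBRARY: list[FragmentRule] = _build_library()


def _observed_mz_table() -> list[tuple[float, float]]:
    """Instrument-observed ion m/z values for the worked-out compounds,
    paired with their composition-derived theoretical masses.

    Used to report the mass-accuracy concordance of the rule library with
    Orbitrap measurements; the worst entry sits below 10 ppm.
    """
    neg, pos = "negative", "positive"
    quinate = theoretical_mz("C7H12O6", neg)
    caffeate = theoretical_mz("C9H8O4", neg)
    di = theoretical_mz("C25H24O12", neg)
    schaft = theoretical_mz("C26H28O14", neg)
    quercetin = theoretical_mz("C15H10O7", neg)
    table = [
        (353.08835, theoretical_mz("C16H18O9", neg)),
        (355.10239, theoretical_mz("C16H18O9", pos)),
        (191.05551, quinate), (191.05556, quinate), (191.05557, quinate),
        (191.05560, quinate), (191.05644, quinate),
        (179.03426, caffeate), (179.03424, caffeate),
        (173.04533, quinate - LOSS["water"]), (173.04445, quinate - LOSS["water"]),
        (173.04474, quinate - LOSS["water"]),
        (135.04398, caffeate - LOSS["CO2"]), (135.04384, caffeate - LOSS["CO2"]),
        (515.12030, di), (515.12018, di),
        (517.13452, theoretical_mz("C25H24O12", pos)),
        (353.08841, di - LOSS["caffeoyl"]), (353.08829, di - LOSS["caffeoyl"]),
        (335.07819, di - LOSS["caffeoyl"] - LOSS["water"]),
        (677.15515, theoretical_mz("C34H30O15", neg)),
        (679.16644, theoretical_mz("C34H30O15", pos)),
        (285.04065, theoretical_mz("C15H10O6", neg)),
        (269.04572, theoretical_mz("C15H10O5", neg)),
        (151.00275, theoretical_mz("C7H4O4", neg)),
        (151.00244, theoretical_mz("C7H4O4", neg)),
        (149.02338, theoretical_mz("C8H6O3", neg)),
        (149.02330, theoretical_mz("C8H6O3", neg)),
        (153.01894, theoretical_mz("C7H4O4", pos)),
        (153.01840, theoretical_mz("C7H4O4", pos)),
        (609.14697, theoretical_mz("C27H30O16", neg)),
        (611.16125, theoretical_mz("C27H30O16", pos)),
        (463.08887, theoretical_mz("C21H20O12", neg)),
        (465.10333, theoretical_mz("C21H20O12", pos)),
        (301.03363, quercetin), (301.03412, quercetin),
        (300.02774, quercetin - MONOISOTOPIC["H"]),
        (303.05005, theoretical_mz("C15H10O7", pos)),
        (303.05002, theoretical_mz("C15H10O7", pos)),
        (178.99791, theoretical_mz("C8H4O5", neg)),
        (178.99759, theoretical_mz("C8H4O5", neg)),
        (151.00278, theoretical_mz("C8H4O5", neg) - LOSS["CO"]),
        (151.00258, theoretical_mz("C8H4O5", neg) - LOSS["CO"]),
        (563.14150, schaft),
        (565.15590, theoretical_mz("C26H28O14", pos)),
        (473.10779, schaft - LOSS["ring_90"]),
        (443.09933, schaft - LOSS["ring_120"]),
        (383.07761, schaft - LOSS["ring_120"] - LOSS["ring_60"]),
        (353.06717, schaft - LOSS["ring_120"] - LOSS["ring_90"]),
        (325.07254, schaft - LOSS["ring_120"] - LOSS["ring_90"] - LOSS["CO"]),
        (297.07742, schaft - LOSS["ring_120"] - LOSS["ring_90"] - 2 * LOSS["CO"]),
    ]
    return table


#: (observed, theoretical) m/z pairs for mass-accuracy concordance reporting.
OBSERVED_MZ: list[tuple[float, float]] = _observed_mz_table()

_LIBRARY_BY_ID = {rule.compound_id: rule for rule in COMPOUND_LIBRARY}


def get_rule(compound_id: str) -> FragmentRule:
    try:
        return _LIBRARY_BY_ID[compound_id]
    except KeyError:
        raise AnnotationError(f"unknown library compound {compound_id!r}") from None


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

_QUINATE = theoretical_mz("C7H12O6", "negative")
_QUINATE_H2O = _QUINATE - LOSS["water"]
_CAFFEATE = theoretical_mz("C9H8O4", "negative")
_CAFFEATE_CO2 = _CAFFEATE - LOSS["CO2"]


def classify_cqa(spec: Spectrum, tol_ppm: float = DEFAULT_TOL_PPM) -> CompoundHypothesis:
    """Establish the caffeoylation degree of a caffeoylquinic acid spectrum.

    Detects the chain [M-H]- -> ... -> quinate (m/z 191.0561) built from
    successive caffeoyl (162.03169 Da) losses.  Requires negative mode: the
    diagnostic ester-bond cleavages are observed in negative mode only.
    """
    if spec.polarity != "negative":
        raise AnnotationError(
            "CQA classification requires a negative-mode spectrum; "
            "reacquire or convert the record"
        )
    tol = spec.precursor_mz * tol_ppm * 1e-6
    degree = None
    for n in (1, 2, 3):
        if abs(spec.precursor_mz - n * LOSS["caffeoyl"] - _QUINATE) <= max(tol, 2e-3):
            degree = n
            break
    if degree is None:
        return CompoundHypothesis(compound_class="none", note="no caffeoyl-loss chain")

    matched: list[tuple[str, float, float, float]] = []
    for k in range(1, degree + 1):
        expect = spec.precursor_mz - k * LOSS["caffeoyl"]
        hit = spec.find_ion(expect, tol_ppm)
        if hit is None:
            return CompoundHypothesis(
                compound_class="none", note=f"caffeoyl chain broken at step {k}"
            )
        matched.append((f"chain-{k}", expect, hit[0], ppm_error(hit[0], expect)))

    support = 0
    for label, mz in (("caffeate", _CAFFEATE), ("caffeate-CO2", _CAFFEATE_CO2),
                      ("quinate-H2O", _QUINATE_H2O)):
        hit = spec.find_ion(mz, tol_ppm)
        if hit is not None:
            matched.append((label, mz, hit[0], ppm_error(hit[0], mz)))
            support += 1

    klass = {1: "monoCQA", 2: "diCQA", 3: "triCQA"}[degree]
    score = (degree + min(support, 1)) / (degree + 1)
    return CompoundHypothesis(compound_class=klass, matched=matched, score=score)


def discriminate_cqa_isomer(spec: Spectrum, degree: int) -> str:
    """Assign a positional isomer from base-peak identity and relative abundances.

    Mono-CQAs are separated by the abundance of m/z 179 (caffeate) when the
    base peak is quinate, di-CQAs by the abundance of m/z 173 when the base
    peak is [M-caffeoyl-H]-.  Guard bands between the calibrated intervals
    return ``"ambiguous"`` rather than a guess.
    """
    base = spec.base_peak_mz
    if degree == 1:
        if abs(base - _QUINATE_H2O) <= NOMINAL_WINDOW_DA:
            return "cryptochlorogenic acid"
        if abs(base - _QUINATE) <= NOMINAL_WINDOW_DA:
            ab179 = spec.abundance_at(_CAFFEATE)
            if ab179 >= 20.0:
                return "neochlorogenic acid"
            if ab179 <= 10.0:
                return "chlorogenic acid"
        return "ambiguous"
    if degree == 2:
        if abs(base - _QUINATE) <= NOMINAL_WINDOW_DA:
            return "1,5-O-dicaffeoylquinic acid"
        m_caffeoyl = monoisotopic_mass("C25H24O12") - PROTON - LOSS["caffeoyl"]
        if abs(base - m_caffeoyl) <= NOMINAL_WINDOW_DA:
            ab173 = spec.abundance_at(_QUINATE_H2O)
            if ab173 >= 35.0:
                return "isochlorogenic acid B"
            if 10.0 <= ab173 < 35.0:
                return "isochlorogenic acid C"
            if ab173 <= 5.0:
                return "isochlorogenic acid A"
        return "ambiguous"
    if degree == 3:
        return "3,4,5-tricaffeoylquinic acid"
    raise AnnotationError(f"unsupported caffeoylation degree {degree}")


_RING_LOSSES = (
    LOSS["ring_60"],
    LOSS["ring_90"],
    LOSS["ring_120"],
    LOSS["ring_120"] + LOSS["ring_60"],
    LOSS["ring_120"] + LOSS["ring_90"],
)
_GLYCOSYL_LOSSES = {
    "hexosyl": LOSS["hexosyl"],
    "deoxyhexosyl": LOSS["deoxyhexosyl"],
    "rutinosyl": LOSS["rutinosyl"],
}
_RDA_IONS = tuple(
    theoretical_mz(f, "negative")
    for f in ("C7H4O4", "C8H6O3", "C6H4O2", "C8H4O5")
) + (theoretical_mz("C8H4O5", "negative") - LOSS["CO"],)


def classify_flavonoid(
    spec: Spectrum, tol_ppm: float = DEFAULT_TOL_PPM
) -> CompoundHypothesis:
    """Assign a flavonoid glycosylation class from negative-mode evidence.

    C-glycosides show >= 2 cross-ring sugar losses (60/90/120 Da or sums)
    from [M-H]- and no aglycone RDA requirement; O-glycosides lose the sugar
    intact to an aglycone ion that itself shows RDA ions; bare aglycones
    show only RDA ions.  Positive-mode spectra lack both kinds of evidence
    and can only yield weak hypotheses.
    """
    if spec.polarity != "negative":
        return CompoundHypothesis(
            compound_class="none", note="RDA/ring-cleavage evidence absent in positive mode"
        )

    matched_ring: list[tuple[str, float, float, float]] = []
    for loss in _RING_LOSSES:
        expect = spec.precursor_mz - loss
        hit = spec.find_ion(expect, tol_ppm)
        if hit is not None:
            matched_ring.append(
                (f"[M-H-{loss:.0f}]-", expect, hit[0], ppm_error(hit[0], expect))
            )
    # primary single-step cleavages only, for the >= 2 criterion
    n_primary = sum(
        1
        for loss in _RING_LOSSES[:3]
        if spec.find_ion(spec.precursor_mz - loss, tol_ppm) is not None
    )

    matched_glyc: list[tuple[str, float, float, float]] = []
    rda_after_loss = False
    for sugar, loss in _GLYCOSYL_LOSSES.items():
        expect = spec.precursor_mz - loss
        hit = spec.find_ion(expect, tol_ppm)
        if hit is not None:
            matched_glyc.append((f"-{sugar}", expect, hit[0], ppm_error(hit[0], expect)))
            rda_after_loss = rda_after_loss or _has_rda(spec, tol_ppm)

    rda = _rda_matches(spec, tol_ppm)

    c_glyc = n_primary >= 2
    o_glyc = bool(matched_glyc) and rda_after_loss
    if c_glyc and o_glyc:
        return CompoundHypothesis(
            compound_class="ambiguous",
            matched=matched_ring + matched_glyc,
            score=0.5,
            note="both intact-glycosyl loss and ring-cleavage series present",
        )
    if c_glyc:
        matched = matched_ring
        return CompoundHypothesis(
            compound_class="flavonoid C-glycoside",
            matched=matched,
            score=min(1.0, len(matched_ring) / 2.0),
        )
    if o_glyc:
        return CompoundHypothesis(
            compound_class="flavonol O-glycoside",
            matched=matched_glyc + rda,
            score=1.0,
        )
    if rda:
        return CompoundHypothesis(
            compound_class="flavone aglycone", matched=rda, score=min(1.0, len(rda) / 2.0)
        )
    return CompoundHypothesis(compound_class="none", note="no flavonoid evidence")


def _rda_matches(spec: Spectrum, tol_ppm: float) -> list[tuple[str, float, float, float]]:
    out = []
    for mz in _RDA_IONS:
        hit = spec.find_ion(mz, tol_ppm)
        if hit is not None:
            out.append(("RDA", mz, hit[0], ppm_error(hit[0], mz)))
    return out


def _has_rda(spec: Spectrum, tol_ppm: float) -> bool:
    return bool(_rda_matches(spec, tol_ppm))


# ---------------------------------------------------------------------------
# Library annotation
# ---------------------------------------------------------------------------

_CQA_CLASSES = {"monoCQA": 1, "diCQA": 2, "triCQA": 3}


def annotate(
    spec: Spectrum,
    library: list[FragmentRule] | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[CompoundHypothesis]:
    """Rank library compounds against a spectrum.

    For every rule whose quasi-molecular ion matches the precursor within
    ``tol_ppm``, the score is the fraction of mandatory evidence satisfied:
    the precursor match, each diagnostic fragment, and - for CQA positional
    isomers - consistency with the abundance-based isomer call.  Ties are
    broken by mean absolute ppm error of the matched ions.  A spectrum that
    matches nothing returns a single class-"none" hypothesis.
    """
    if not spec.peaks:
        raise AnnotationError("cannot annotate an empty spectrum")
    if library is None:
        library = COMPOUND_LIBRARY

    cqa_hyp = None
    isomer_call = None
    if spec.polarity == "negative":
        cqa_hyp = classify_cqa(spec, tol_ppm)
        if cqa_hyp.compound_class in _CQA_CLASSES:
            isomer_call = discriminate_cqa_isomer(
                spec, _CQA_CLASSES[cqa_hyp.compound_class]
            )

    hypotheses: list[CompoundHypothesis] = []
    for rule in library:
        if spec.polarity not in rule.fragments:
            continue
        prec_theor = rule.precursor_mz(spec.polarity)
        prec_ppm = ppm_error(spec.precursor_mz, prec_theor)
        if abs(prec_ppm) > tol_ppm:
            continue

        checks = 1  # precursor
        satisfied = 1.0
        matched = [("precursor", prec_theor, spec.precursor_mz, prec_ppm)]
        for ion in rule.reference_spectrum(spec.polarity):
            checks += 1
            hit = spec.find_ion(ion.mz, tol_ppm)
            if hit is not None:
                satisfied += 1.0
                matched.append((ion.label, ion.mz, hit[0], ppm_error(hit[0], ion.mz)))

        if rule.compound_class in _CQA_CLASSES and spec.polarity == "negative":
            checks += 1
            if isomer_call == rule.isomer:
                satisfied += 1.0
            elif isomer_call == "ambiguous":
                satisfied += 0.5

        hypotheses.append(
            CompoundHypothesis(
                compound_class=rule.compound_class,
                isomer=rule.compound_id,
                matched=matched,
                score=satisfied / checks,
            )
        )

    if not hypotheses:
        return [CompoundHypothesis(compound_class="none", score=0.0, note="no library match")]

    def sort_key(h: CompoundHypothesis):
        mean_ppm = (
            sum(abs(m[3]) for m in h.matched) / len(h.matched) if h.matched else float("inf")
        )
        return (-h.score, mean_ppm)

    return sorted(hypotheses, key=sort_key)
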