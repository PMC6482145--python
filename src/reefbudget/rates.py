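"""Calcification and bioerosion rate tables.

Calcification rates Ci are keyed by (taxon, morphology) in g cm^-2 yr^-1;
lookups fall back to a morphology-level default unless strict mode is on.
Bioerosion constants cover endolithic borers (G per unit rugosity-scaled
available substrate), parrotfish (G applied to planar available substrate)
and the per-genus echinoid power law rate = a * X^b with X the test size
in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .survey import MORPHOLOGIES, SurveyError

__all__ = ["RateTable", "DEFAULT_MORPHOLOGY_CI", "ECHINOID_SIZE_EXPONENT"]

#: Shared exponent of the echinoid test-size power law.
ECHINOID_SIZE_EXPONENT = 1.6624

#: Diadema coefficient of the echinoid power law.
DIADEMA_COEFF = 0.0029

#: Phyllocanthus coefficient.  The source power law is widely printed with
#: the exponent sign lost (8e5), which would make a single 90 mm urchin
#: erode thousands of kg of carbonate a year; 8e-5 is the physically
#: coherent magnitude and is the default here.  See RateTable.verbatim
#: below for the literal printed value.
PHYLLOCANTHUS_COEFF = 8.0e-5
PHYLLOCANTHUS_COEFF_VERBATIM = 8.0e5

# Placeholder morphology-level calcification defaults (g cm^-2 yr^-1).
# These are representative Indo-Pacific-style magnitudes for reef-flat
# communities, NOT a transcription of any published rate compilation;
# quantitative analyses should inject an explicit table.
DEFAULT_MORPHOLOGY_CI: dict[str, float] = {
    "massive": 1.0,
    "branching": 2.1,
    "tabular": 2.0,
    "digitate": 1.5,
    "encrusting": 0.8,
    "free_living": 0.8,
}

DEFAULT_CALCIFICATION: dict[tuple[str, str], float] = {
    ("Porites", "massive"): 1.1,
    ("Acropora", "branching"): 2.6,
    ("Heliopora", "branching"): 1.5,
    ("CCA", "encrusting"): 0.4,
}


@dataclass(frozen=True)
class RateTable:
    """All rate constants the budget needs, with validated invariants.

    Attributes
    ----------
    calcification : dict
        (taxon, morphology) -> Ci in g cm^-2 yr^-1.
    morphology_defaults : dict
        morphology -> fallback Ci used when a (taxon, morphology) pair is
        absent (e.g. unidentified genera).
    macro_borer_rate, micro_borer_rate : float
        Endolithic erosion constants in G per unit of rugosity-scaled
        available substrate; applied summed.
    parrotfish_rate : float
        Parrotfish erosion in G applied to fully available planar substrate.
    echinoid_coeffs : dict
        genus -> (a, b) of the test-size power law a * X^b.
    cca_ci : float
        Ci for crustose coralline algae (secondary producer).
    halimeda_ci : float or None
        Optional Ci for Halimeda macroalgae; ``None`` (default) means
        macroalgae contribute no production.
    strict : bool
        If True, a missing (taxon, morphology) entry raises instead of
        falling back to the morphology default.
    """

    calcification: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CALCIFICATION)
    )
    morphology_defaults: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY_CI)
    )
    macro_borer_rate: float = 0.052
    micro_borer_rate: float = 0.053
    parrotfish_rate: float = 3.81
    echinoid_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Diadema": (DIADEMA_COEFF, ECHINOID_SIZE_EXPONENT),
            "Phyllocanthus": (PHYLLOCANTHUS_COEFF, ECHINOID_SIZE_EXPONENT),
        }
    )
    cca_ci: float = 0.4
    halimeda_ci: float | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        for key, ci in self.calcification.items():
            if not ci > 0:
                raise SurveyError(f"calcification rate for {key} must be > 0, got {ci}")
        for morph, ci in self.morphology_defaults.items():
            if morph not in MORPHOLOGIES or morph == "none":
                raise SurveyError(f"morphology default for unknown morphology {morph!r}")
            if not ci > 0:
                raise SurveyError(f"morphology default Ci must be > 0, got {ci}")
        for name in ("macro_borer_rate", "micro_borer_rate", "parrotfish_rate", "cca_ci"):
            if getattr(self, name) < 0:
                raise SurveyError(f"{name} must be >= 0")
        for genus, (a, b) in self.echinoid_coeffs.items():
            if a < 0:
                raise SurveyError(f"echinoid coefficient a for {genus!r} must be >= 0")
            if b <= 0:
                raise SurveyError(f"echinoid exponent b for {genus!r} must be > 0")

    @classmethod
    def default(cls) -> "RateTable":
        """The placeholder default table (see DEFAULT_MORPHOLOGY_CI note)."""
        return cls()

    def verbatim_phyllocanthus(self) -> "RateTable":
        """Return a copy using the literal printed Phyllocanthus coefficient.

        Exact-source mode: the coefficient 8e5 yields physically absurd
        rates and exists only for reproducing the printed formula as-is.
        """
        coeffs = dict(self.echinoid_coeffs)
        coeffs["Phyllocanthus"] = (PHYLLOCANTHUS_COEFF_VERBATIM, ECHINOID_SIZE_EXPONENT)
        return replace(self, echinoid_coeffs=coeffs)

    def lookup_ci(self, taxon: str | None, morphology: str) -> float:
        """Resolve Ci for a producer point, with morphology-level fallback."""
        if taxon is not None and (taxon, morphology) in self.calcification:
            return self.calcification[(taxon, morphology)]
        if not self.strict and morphology in self.morphology_defaults:
            return self.morphology_defaults[morphology]
        raise SurveyError(
            f"no calcification rate for taxon {taxon!r} with morphology "
            f"{morphology!r}"
            + ("" if self.strict else " and no morphology-level default")
        )

    @classmethod
    def from_csv(cls, path, **overrides) -> "RateTable":
        """Build a table from a rates CSV (taxon,morphology,ci_g_cm2_yr,source).

        Rows with taxon ``"*"`` define morphology-level defaults.  Keyword
        overrides set the scalar erosion constants.
        """
        df = pd.read_csv(path)
        required = {"taxon", "morphology", "ci_g_cm2_yr"}
        missing = required - set(df.columns)
        if missing:
            raise SurveyError(f"rates CSV missing column(s): {sorted(missing)}")
        calcification: dict[tuple[str, str], float] = {}
        morphology_defaults: dict[str, float] = {}
        for i, row in df.iterrows():
            taxon = str(row["taxon"]).strip()
            morph = str(row["morphology"]).strip()
            try:
                ci = float(row["ci_g_cm2_yr"])
            except (TypeError, ValueError) as exc:
                raise SurveyError(f"rates CSV row {i + 2}: bad Ci value") from exc
            if taxon == "*":
                morphology_defaults[morph] = ci
            else:
                calcification[(taxon, morph)] = ci
        kwargs = dict(
            calcification=calcification,
            morphology_defaults=morphology_defaults or dict(DEFAULT_MORPHOLOGY_CI),
        )
        if ("CCA", "encrusting") in calcification:
            kwargs["cca_ci"] = calcification[("CCA", "encrusting")]
        kwargs.update(overrides)
        return cls(**kwargs)
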