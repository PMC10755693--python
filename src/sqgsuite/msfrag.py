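"""Mass arithmetic and deuterium label-position inference for SQ fragment ions.

When an SQ glycoside is hydrolysed in D2O by an NAD+-dependent SQase, the
oxidoreductive mechanism deposits one non-exchangeable deuterium on the sugar.
Negative-mode tandem MS of the [M−H]⁻ ion then localises it: fragment ions
whose m/z does not shift cannot contain the label on any carbon they cover,
while a neutral-loss pathway that erases the shift (labelled and unlabelled
precursors converging on the same product m/z) pins the label to the atoms
taking part in that loss.  ``infer_label_position`` propagates these
constraints to a feasible set of sugar carbons.

Masses: *nominal* uses integer mass numbers; *monoisotopic* uses IUPAC 2021
isotope masses with the electron mass included for ions.  Deuterium is
book-kept separately from hydrogen so that a +1 nominal shift is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

ELEMENTS = ("C", "H", "D", "N", "O", "S")

NOMINAL_MASS = {"C": 12, "H": 1, "D": 2, "N": 14, "O": 16, "S": 32}

# IUPAC/AME2020 monoisotopic masses (u)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177812,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.000548579909


@dataclass(frozen=True)
class Formula:
    """An elemental formula over {C,H,D,N,O,S} with an integer charge.

    D is counted separately from H: ``deuterate`` moves counts from H to D.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"cannot subtract {other}: negative {el} count"
                )
        return Formula(merged, self.charge - other.charge)

    def __str__(self) -> str:
        body = "".join(
            f"{el}{self.counts[el]}" for el in ELEMENTS if el in self.counts
        )
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += f" [{abs(self.charge)}{sign}]"
        return body or "(empty)"


def formula(spec: str | Mapping[str, int], charge: int = 0) -> Formula:
    """Build a Formula from a mapping or a compact string like ``C6H12O8S``."""
    if isinstance(spec, Mapping):
        return Formula(dict(spec), charge)
    import re

    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", spec):
        if not el:
            continue
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return Formula(counts, charge)


#: sulfoquinovose, C6H12O8S — [M−H]⁻ at nominal m/z 243
SQ = formula("C6H12O8S")
#: sulfoquinovosyl glycerol, C9H18O10S — [M−H]⁻ at nominal m/z 317
SQGRO = formula("C9H18O10S")

WATER = formula("H2O")
HOD = Formula({"H": 1, "D": 1, "O": 1})


def mass(f: Formula, mode: str = "nominal") -> float:
    """Mass of a formula; for ions, the m/z (electron mass included in
    monoisotopic mode; nominal masses are pure integer sums)."""
    if mode == "nominal":
        m = float(sum(NOMINAL_MASS[el] * n for el, n in f.counts.items()))
    elif mode == "monoisotopic":
        m = sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())
        m -= f.charge * ELECTRON_MASS
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if f.charge:
        return m / abs(f.charge)
    return m


def deprotonate(f: Formula) -> Formula:
    """[M−H]⁻: remove one proton, charge −1 relative to input."""
    if f["H"] < 1:
        raise ValueError("no H to remove")
    counts = dict(f.counts)
    counts["H"] -= 1
    return Formula(counts, f.charge - 1)


def deuterate(f: Formula, n: int = 1) -> Formula:
    """Replace ``n`` hydrogens by deuterium; nominal mass rises by exactly n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > f["H"]:
        raise ValueError(f"cannot deuterate {n} H: formula has {f['H']}")
    counts = dict(f.counts)
    counts["H"] = counts.get("H", 0) - n
    counts["D"] = counts.get("D", 0) + n
    return Formula(counts, f.charge)


CARBONS = frozenset(range(1, 7))


@dataclass(frozen=True)
class FragmentIon:
    """A fragment ion and the parent-sugar carbons it retains.

    ``carbon_coverage`` is declared data (which of C1..C6 the ion contains);
    the inference engine consumes the declaration rather than deriving it from
    fragmentation chemistry, so the chemical assumptions stay visible and
    editable.  Masses are computed when a formula is given, otherwise the
    observed nominal m/z may be supplied directly.
    """

    label: str
    carbon_coverage: frozenset[int]
    formula: Formula | None = None
    nominal_mz: float | None = None
    monoisotopic_mz: float | None = None

    def __post_init__(self) -> None:
        cov = frozenset(int(c) for c in self.carbon_coverage)
        if not cov <= CARBONS:
            raise ValueError(f"coverage {sorted(cov)} outside C1..C6")
        object.__setattr__(self, "carbon_coverage", cov)
        if self.formula is not None:
            if self.nominal_mz is None:
                object.__setattr__(self, "nominal_mz", mass(self.formula, "nominal"))
            if self.monoisotopic_mz is None:
                object.__setattr__(
                    self, "monoisotopic_mz", mass(self.formula, "monoisotopic")
                )


def apply_losses(ion: FragmentIon, losses: Sequence[Formula]) -> FragmentIon:
    """Subtract neutral losses sequentially, updating formula and masses."""
    if ion.formula is None:
        raise ValueError("apply_losses requires an ion with a formula")
    f = ion.formula
    for loss in losses:
        f = f - replace(loss, charge=0)
    label = ion.label + "".join(f"-{loss}" for loss in losses)
    return FragmentIon(
        label=label, carbon_coverage=ion.carbon_coverage, formula=f
    )


@dataclass(frozen=True)
class LabelObservation:
    """An observed labelled-vs-unlabelled m/z shift for one fragment.

    ``delta_mz`` is the integer shift of this ion between spectra of the
    labelled and unlabelled species (0 or 1 for single-deuterium work).
    ``loss_atoms``, when given, are the sugar carbons whose hydrons take part
    in the neutral losses forming this ion; a shift of 0 *with* loss atoms
    records convergence of labelled and unlabelled precursors onto the same
    product m/z (the label left with the loss).
    """

    fragment_label: str
    delta_mz: int
    loss_atoms: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.delta_mz not in (0, 1):
            raise ValueError("delta_mz must be 0 or 1 for single-D experiments")
        if self.loss_atoms is not None:
            la = frozenset(int(c) for c in self.loss_atoms)
            if not la <= CARBONS:
                raise ValueError(f"loss atoms {sorted(la)} outside C1..C6")
            object.__setattr__(self, "loss_atoms", la)


@dataclass(frozen=True)
class LabelInference:
    feasible: frozenset[int]
    status: str  # "ok" | "no label detected" | "inconsistent"
    per_observation: tuple[tuple[str, frozenset[int]], ...] = ()


def _feasible_for(obs: LabelObservation, coverage: frozenset[int]) -> frozenset[int]:
    """Carbons consistent with one observation, under a single-label model.

    Predicted shift for label on carbon c: 1 if c is covered by the ion and
    not removed by a loss, else 0.  The feasible set is the carbons whose
    prediction matches the observed shift.
    """
    loss = obs.loss_atoms or frozenset()
    retained = coverage - loss
    if obs.delta_mz == 1:
        return retained
    return CARBONS - retained


def infer_label_position(
    fragments: Iterable[FragmentIon],
    observations: Iterable[LabelObservation],
) -> LabelInference:
    """Constraint propagation over shift observations to a feasible carbon set.

    Rules, applied as intersections over the single-label hypotheses C1..C6:

    - an unchanged fragment (Δ=0, no loss) excludes every carbon it covers;
    - a shifted ion (Δ=1) asserts the label lies on a covered carbon that no
      loss removed;
    - an unchanged ion formed via a loss pathway (Δ=0 with loss atoms)
      restricts the label to atoms outside the ion's coverage or inside the
      loss.

    Returns the intersection; an empty set carries status ``inconsistent``,
    or ``no label detected`` when no observation showed any shift.
    """
    frag_by_label = {f.label: f for f in fragments}
    observations = list(observations)
    for obs in observations:
        if obs.fragment_label not in frag_by_label:
            raise KeyError(f"observation references unknown fragment "
                           f"{obs.fragment_label!r}")
    if not any(o.delta_mz == 1 for o in observations):
        return LabelInference(frozenset(), "no label detected")

    feasible = frozenset(CARBONS)
    trail = []
    for obs in observations:
        cov = frag_by_label[obs.fragment_label].carbon_coverage
        allowed = _feasible_for(obs, cov)
        feasible &= allowed
        trail.append((obs.fragment_label, allowed))
    status = "ok" if feasible else "inconsistent"
    return LabelInference(feasible, status, tuple(trail))


# --- fixture: the SQ [M−H]⁻ fragment scheme -------------------------------
# Carbon-coverage assignments for the 123/153/183 series are figure-derived
# fixture data, not computed from fragmentation chemistry.  What the
# experiment uses is that the three unchanged ions jointly cover C3–C6.
SQ_MH = deprotonate(SQ)  # nominal m/z 243

SQ_FRAGMENT_TABLE: tuple[FragmentIon, ...] = (
    FragmentIon("M-H", CARBONS, formula=SQ_MH),
    FragmentIon("207", CARBONS, formula=SQ_MH - WATER - WATER),
    FragmentIon("183", frozenset({3, 4, 5, 6}), nominal_mz=183.0),
    FragmentIon("153", frozenset({4, 5, 6}), nominal_mz=153.0),
    FragmentIon("123", frozenset({5, 6}), nominal_mz=123.0),
)

#: the published observation set: molecular ion shifts by +1; 123/153/183 are
#: unchanged; 244→207 proceeds via HOD loss across C2–C3 plus H2O across C4–C5
SQ_D2O_OBSERVATIONS: tuple[LabelObservation, ...] = (
    LabelObservation("M-H", delta_mz=1),
    LabelObservation("183", delta_mz=0),
    LabelObservation("153", delta_mz=0),
    LabelObservation("123", delta_mz=0),
    LabelObservation("207", delta_mz=0, loss_atoms=frozenset({2, 3})),
)
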