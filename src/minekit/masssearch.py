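"""Accurate-mass annotation of LC-MS peak lists against a compound database.

Each peak's observed m/z is searched against the theoretical m/z of every
(compound, adduct) pair of matching polarity within a user tolerance
(mDa or ppm). Candidates can be filtered by optional per-compound property
annotations (logP, Kovats retention index) and flagged when present in an
organism-specific compound set. The candidate index is a mass-sorted array
with binary-search windows per adduct.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from minekit.datastore import DatabaseBundle
from minekit.registry import ELECTRON_MASS, PROTON_MASS, formula_mass

log = logging.getLogger(__name__)

POSITIVE = "+"
NEGATIVE = "-"
_POLARITY_ALIASES = {
    "+": POSITIVE, "pos": POSITIVE, "positive": POSITIVE, "1": POSITIVE,
    "-": NEGATIVE, "−": NEGATIVE, "neg": NEGATIVE, "negative": NEGATIVE, "-1": NEGATIVE,
}


@dataclass(frozen=True)
class Adduct:
    """A named ionization transform mapping neutral mass to observed m/z.

    ``mass_shift`` is signed and includes the electron-mass correction;
    all standard singly charged adducts have multiplicity 1.
    """

    name: str
    polarity: str
    mass_shift: float
    multiplicity: int = 1

    def mz(self, neutral_mass: float) -> float:
        return self.multiplicity * neutral_mass + self.mass_shift

    def neutral_mass(self, mz: float) -> float:
        return (mz - self.mass_shift) / self.multiplicity


def adduct_table() -> list[Adduct]:
    """The standard adduct set for protonated/sodiated/radical/deprotonated/acetate ions.

    Shifts are exact consequences of the particle and formula masses:
    [M+H]+ adds a proton (H atom minus its electron); [M+]+ loses one
    electron; [M+Na]+ adds Na minus an electron; [M-H]- removes a proton;
    [M+CH3COO]- adds acetic acid minus a proton.
    """
    sodium = formula_mass("Na")
    acetic = formula_mass("C2H4O2")
    return [
        Adduct("[M+H]+", POSITIVE, PROTON_MASS),
        Adduct("[M+Na]+", POSITIVE, sodium - ELECTRON_MASS),
        Adduct("[M+]+", POSITIVE, -ELECTRON_MASS),
        Adduct("[M-H]-", NEGATIVE, -PROTON_MASS),
        Adduct("[M+CH3COO]-", NEGATIVE, acetic - PROTON_MASS),
    ]


_ADDUCTS_BY_NAME = {a.name: a for a in adduct_table()}
# tolerate the typographic minus of formatted documents
_ADDUCT_ALIASES = {"[M−H]−": "[M-H]-", "[M+CH3COO]−": "[M+CH3COO]-"}


def get_adduct(name: str) -> Adduct:
    name = _ADDUCT_ALIASES.get(name.strip(), name.strip())
    try:
        return _ADDUCTS_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; known: {sorted(_ADDUCTS_BY_NAME)}"
        ) from None


def theoretical_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Observed m/z of a neutral monoisotopic mass under an adduct (charge 1)."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return adduct.mz(neutral_mass)


def neutral_candidates(
    mz: float, adducts: list[Adduct] | None = None
) -> list[tuple[Adduct, float]]:
    """Invert an observed m/z to (adduct, neutral mass) hypotheses."""
    adducts = adducts if adducts is not None else adduct_table()
    out = []
    for adduct in adducts:
        mass = adduct.neutral_mass(mz)
        if mass > 0:
            out.append((adduct, mass))
    return out


@dataclass
class Peak:
    """An observed accurate mass with ionization polarity."""

    peak_id: str
    mz: float
    polarity: str
    retention: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak {self.peak_id}: m/z must be positive, got {self.mz}")
        self.polarity = _POLARITY_ALIASES.get(str(self.polarity).strip().lower(), self.polarity)


@dataclass
class SearchHit:
    """A candidate compound matched to a peak via an adduct within tolerance."""

    peak_id: str
    adduct: str
    compound_id: str
    theoretical_mz: float
    error_mda: float  # signed, observed - theoretical
    in_organism: bool = False


@dataclass
class SearchConfig:
    """Tolerance, adduct subset and optional candidate filters.

    Tolerance is one of mDa (mirroring instrument-precision conventions)
    or ppm, never both. Property-range filters apply only to compounds
    carrying the annotation; ``unannotated_pass`` decides whether compounds
    without it pass (default) or fail.
    """

    tolerance_mda: float | None = 2.0
    tolerance_ppm: float | None = None
    adducts: list[str] = field(default_factory=lambda: [a.name for a in adduct_table()])
    logp_range: tuple[float, float] | None = None
    ri_range: tuple[float, float] | None = None
    organism_ids: set[str] | None = None
    unannotated_pass: bool = True

    def __post_init__(self) -> None:
        if (self.tolerance_mda is None) == (self.tolerance_ppm is None):
            raise ValueError("specify exactly one of tolerance_mda / tolerance_ppm")
        tol = self.tolerance_mda if self.tolerance_mda is not None else self.tolerance_ppm
        if tol <= 0:
            raise ValueError(f"tolerance must be positive, got {tol}")

    def tolerance_da(self, mz: float) -> float:
        if self.tolerance_mda is not None:
            return self.tolerance_mda * 1e-3
        return self.tolerance_ppm * 1e-6 * mz


def _passes_property_filters(comp, config: SearchConfig) -> bool:
    for key, rng in (("logp", config.logp_range), ("kovats_ri", config.ri_range)):
        if rng is None:
            continue
        value = comp.properties.get(key)
        if value is None:
            if not config.unannotated_pass:
                return False
        elif not rng[0] <= value <= rng[1]:
            return False
    return True


def search_peaks(
    bundle: DatabaseBundle, peaks: list[Peak], config: SearchConfig | None = None
) -> dict[str, list[SearchHit]]:
    """Annotate peaks with all (compound, adduct) candidates within tolerance.

    Hits per peak are sorted by |error| ascending, ties by compound_id; the
    organism flag is set for compounds in ``config.organism_ids``. Peaks
    with unrecognized polarity are skipped with a warning.
    """
    config = config or SearchConfig()
    adducts = [get_adduct(name) for name in config.adducts]

    cids = sorted(bundle.compounds)
    masses = np.array([bundle.compounds[c].exact_mass for c in cids])
    order = np.argsort(masses, kind="stable")
    masses = masses[order]
    cids = [cids[i] for i in order]

    results: dict[str, list[SearchHit]] = {}
    for peak in peaks:
        if peak.polarity not in (POSITIVE, NEGATIVE):
            log.warning("peak %s: unparseable polarity %r; skipped", peak.peak_id, peak.polarity)
            continue
        hits: list[SearchHit] = []
        tol = config.tolerance_da(peak.mz)
        for adduct in adducts:
            if adduct.polarity != peak.polarity:
                continue
            center = adduct.neutral_mass(peak.mz)
            half = tol / adduct.multiplicity
            lo = int(np.searchsorted(masses, center - half, side="left"))
            hi = int(np.searchsorted(masses, center + half, side="right"))
            for i in range(lo, hi):
                comp = bundle.compounds[cids[i]]
                if not _passes_property_filters(comp, config):
                    continue
                theo = adduct.mz(comp.exact_mass)
                error = peak.mz - theo
                if abs(error) > tol + 1e-12:
                    continue  # pragma: no cover - window already bounds the error
                hits.append(
                    SearchHit(
                        peak_id=peak.peak_id,
                        adduct=adduct.name,
                        compound_id=comp.compound_id,
                        theoretical_mz=theo,
                        error_mda=error * 1e3,
                        in_organism=bool(
                            config.organism_ids and comp.compound_id in config.organism_ids
                        ),
                    )
                )
        # |error| rounded to 1e-6 mDa so exact-mass isomers are true ties,
        # broken by compound_id, not by summation-order float noise
        hits.sort(key=lambda h: (round(abs(h.error_mda), 6), h.compound_id, h.adduct))
        results[peak.peak_id] = hits
    return results


class PeakListError(ValueError):
    """A peak-list CSV is malformed."""


def read_peaklist(path: str | Path) -> list[Peak]:
    """Load peaks from CSV with header ``peak_id,mz,polarity`` (extras ignored)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in ("peak_id", "mz", "polarity") if c not in fields]
        if missing:
            raise PeakListError(f"{path}: missing required column(s) {missing}")
        peaks = []
        for i, row in enumerate(reader, start=2):
            try:
                peaks.append(
                    Peak(
                        peak_id=row["peak_id"].strip(),
                        mz=float(row["mz"]),
                        polarity=row["polarity"],
                    )
                )
            except (TypeError, ValueError) as exc:
                raise PeakListError(f"{path}: row {i}: {exc}") from exc
    return peaks


RESULT_COLUMNS = [
    "peak_id", "mz", "adduct", "compound_id", "mine_number", "formula",
    "theoretical_mz", "error_mda", "inchikey", "smiles", "in_organism",
]


def write_results(
    hits: dict[str, list[SearchHit]],
    bundle: DatabaseBundle,
    peaks: list[Peak],
    path: str | Path,
) -> None:
    """Write annotation results as a spreadsheet-compatible CSV."""
    mz_by_peak = {p.peak_id: p.mz for p in peaks}
    order = {p.peak_id: i for i, p in enumerate(peaks)}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for peak_id in sorted(hits, key=lambda p: order.get(p, len(order))):
            for h in hits[peak_id]:
                comp = bundle.compounds[h.compound_id]
                writer.writerow(
                    [
                        h.peak_id,
                        f"{mz_by_peak.get(peak_id, float('nan')):.4f}",
                        h.adduct,
                        h.compound_id,
                        comp.mine_number,
                        comp.formula,
                        f"{h.theoretical_mz:.6f}",
                        f"{h.error_mda:.3f}",
                        comp.inchikey,
                        comp.smiles,
                        int(h.in_organism),
                    ]
                )
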