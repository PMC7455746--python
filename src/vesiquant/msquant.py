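"""Targeted-MS quantification: calibration, isotope bookkeeping, stoichiometry.

Integrated MRM peak counts are averaged over duplicate injections, converted
to concentrations through a linear calibration fitted to a dilution series
of standards run before and after the samples, and summarised as lipid-class
compositions and an acyl-CoA conversion yield.

De novo synthesized lipids are distinguished from pre-existing membrane
lipids by a heavy glycerol-3-phosphate precursor: uniformly 13C-labelled
G3P carries three heavy carbons, so every G3P-derived moiety adds a nominal
+3 Da.  PG (and its phosphorylated precursor PGP) incorporate two G3P units
— one as the diacylglycerol backbone, one as the headgroup glycerol — and
therefore shift by +6 Da; all single-G3P lipids (PA, PE, PS, CDP-DAG, LPA)
shift by +3 Da.

Acyl-chain bookkeeping: with palmitoyl (16:0) and oleoyl (18:1) CoA
precursors, diacyl products are dipalmitoyl (DP), dioleoyl (DO) or mixed
palmitoyl-oleoyl (PO).  If chains were incorporated at random with 16:0
fraction p, the expected composition is DP = p^2, DO = (1-p)^2,
PO = 2 p (1-p) — 50% PO at equimolar precursors.  Each diacyl product
consumes two acyl-CoA molecules, so the conversion yield is
100 * sum_i conc_i * n_chains_i / [acyl-CoA]_0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidSpecies",
    "IsotopeLabel",
    "CalibrationFit",
    "DEFAULT_SPECIES",
    "average_injections",
    "fit_calibration",
    "counts_to_concentration",
    "normalize_to_reference_peptide",
    "isotope_mass_shift",
    "chain_composition_fractions",
    "random_incorporation_null",
    "conversion_yield",
    "quantify_samples",
]


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid analyte: chains, G3P-moiety count, pathway role."""

    id: str
    headgroup_class: str
    chain1: str  # "16:0", "18:1" or "none"
    chain2: str
    n_acyl_chains: int
    n_g3p_moieties: int
    is_end_product: bool

    def __post_init__(self) -> None:
        if self.n_acyl_chains not in (1, 2):
            raise ValueError("n_acyl_chains must be 1 or 2")
        if self.n_g3p_moieties not in (1, 2):
            raise ValueError("n_g3p_moieties must be 1 or 2")
        if self.headgroup_class in ("PG", "PGP") and self.n_g3p_moieties != 2:
            raise ValueError(f"{self.headgroup_class} must carry 2 G3P moieties")


def _sp(id, hg, c1, c2, nch, ng3p, end):
    return LipidSpecies(id, hg, c1, c2, nch, ng3p, end)


# Kennedy-pathway analytes: PG/PGP carry two G3P-derived glycerols (backbone
# plus headgroup), everything else one; LPA is the single-chain intermediate.
DEFAULT_SPECIES: dict[str, LipidSpecies] = {
    s.id: s
    for s in [
        _sp("DOPE", "PE", "18:1", "18:1", 2, 1, True),
        _sp("POPE", "PE", "16:0", "18:1", 2, 1, True),
        _sp("DPPE", "PE", "16:0", "16:0", 2, 1, True),
        _sp("DOPG", "PG", "18:1", "18:1", 2, 2, True),
        _sp("POPG", "PG", "16:0", "18:1", 2, 2, True),
        _sp("DPPG", "PG", "16:0", "16:0", 2, 2, True),
        _sp("DOPS", "PS", "18:1", "18:1", 2, 1, True),
        _sp("DOPA", "PA", "18:1", "18:1", 2, 1, False),
        _sp("DPPA", "PA", "16:0", "16:0", 2, 1, False),
        _sp("LPA", "LPA", "18:1", "none", 1, 1, False),
        _sp("CDP-DAG", "CDP-DAG", "18:1", "18:1", 2, 1, False),
        _sp("PGP", "PGP", "18:1", "18:1", 2, 2, False),
    ]
}


@dataclass(frozen=True)
class IsotopeLabel:
    """Heavy-precursor description; default: uniformly 13C-labelled G3P."""

    precursor: str = "13C-G3P"
    heavy_atoms_per_moiety: int = 3
    mass_increment_per_atom_da: float = 1.003355  # 13C - 12C

    def __post_init__(self) -> None:
        if self.heavy_atoms_per_moiety < 0:
            raise ValueError("heavy_atoms_per_moiety must be >= 0")
        if self.mass_increment_per_atom_da <= 0:
            raise ValueError("mass_increment_per_atom_da must be positive")


@dataclass(frozen=True)
class CalibrationFit:
    """Linear detector response for one species: counts = slope*conc + intercept."""

    species_id: str
    slope_counts_per_uM: float
    intercept_counts: float
    r_squared: float
    levels_uM: tuple[float, ...]


def average_injections(table: pd.DataFrame) -> pd.DataFrame:
    """Average counts over replicate injections of each (sample, transition).

    Returns one row per (sample_id, transition_id, block) with the mean
    counts and the number of injections averaged (``n_injections``); all
    other columns are carried through from the first row of each group.
    """
    required = {"sample_id", "transition_id", "injection", "counts"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    keys = ["sample_id", "transition_id"]
    if "block" in table.columns:
        keys.append("block")
    grouped = table.groupby(keys, sort=False)
    out = grouped.first().reset_index()
    out["counts"] = grouped["counts"].mean().to_numpy()
    out["n_injections"] = grouped.size().to_numpy()
    return out.drop(columns=["injection"])


def fit_calibration(standards: pd.DataFrame, species_id: str) -> CalibrationFit:
    """OLS calibration line for one species over pooled pre+post standards.

    ``standards`` must carry a ``concentration_uM`` column; duplicate
    injections are averaged first and both calibration blocks contribute
    points to a single ordinary-least-squares fit.
    """
    if "concentration_uM" not in standards.columns:
        raise ValueError("standards table needs a concentration_uM column")
    rows = standards[standards["transition_id"] == species_id]
    if rows.empty:
        raise ValueError(f"no calibration rows for species {species_id!r}")
    avg = average_injections(rows)
    conc = avg["concentration_uM"].to_numpy(dtype=float)
    counts = avg["counts"].to_numpy(dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct calibration levels")
    res = stats.linregress(conc, counts)
    return CalibrationFit(
        species_id=species_id,
        slope_counts_per_uM=float(res.slope),
        intercept_counts=float(res.intercept),
        r_squared=float(res.rvalue**2),
        levels_uM=tuple(sorted(np.unique(conc))),
    )


def counts_to_concentration(counts, fit: CalibrationFit):
    """Invert the calibration: (counts - intercept) / slope, clamped at 0.

    Returns ``(concentration_uM, clamped)``; ``clamped`` flags values that
    back-calculated negative (sub-blank signal) and were set to 0.  Scalars
    in give scalars out.
    """
    if fit.slope_counts_per_uM <= 0:
        raise ValueError("calibration slope must be positive")
    arr = np.asarray(counts, dtype=float)
    conc = (arr - fit.intercept_counts) / fit.slope_counts_per_uM
    clamped = conc < 0
    conc = np.where(clamped, 0.0, conc)
    if np.isscalar(counts) or arr.ndim == 0:
        return float(conc), bool(clamped)
    return conc, clamped


def normalize_to_reference_peptide(peptide_counts, reference_counts: float):
    """Peptide signal normalized to a constant internal-standard peptide.

    Used to correct tryptic-peptide intensities for evaporation and handling
    via an invariant reference (an EF-Tu peptide present in every sample).
    """
    if not np.isfinite(reference_counts) or reference_counts <= 0:
        raise ValueError("reference peptide counts must be positive")
    arr = np.asarray(peptide_counts, dtype=float)
    out = arr / reference_counts
    if np.isscalar(peptide_counts) or arr.ndim == 0:
        return float(out)
    return out


def isotope_mass_shift(
    species: LipidSpecies | str,
    label: IsotopeLabel | None = None,
    rounding: str = "nominal",
) -> float:
    """Mass shift of the de novo product relative to the unlabeled species.

    Each G3P-derived moiety contributes ``heavy_atoms_per_moiety`` heavy
    carbons; nominal mode counts 1 Da per heavy atom (+3 Da for single-G3P
    lipids, +6 Da for PG), exact mode uses the 13C-12C mass difference.
    """
    if isinstance(species, str):
        try:
            species = DEFAULT_SPECIES[species]
        except KeyError:
            raise ValueError(f"unknown lipid species {species!r}") from None
    label = label or IsotopeLabel()
    if rounding not in ("nominal", "exact"):
        raise ValueError("rounding must be 'nominal' or 'exact'")
    n_atoms = species.n_g3p_moieties * label.heavy_atoms_per_moiety
    per_atom = 1.0 if rounding == "nominal" else label.mass_increment_per_atom_da
    return n_atoms * per_atom


def _chain_category(species: LipidSpecies) -> str | None:
    if species.n_acyl_chains != 2:
        return None
    chains = {species.chain1, species.chain2}
    if chains == {"16:0"}:
        return "DP"
    if chains == {"18:1"}:
        return "DO"
    if chains == {"16:0", "18:1"}:
        return "PO"
    return None


def random_incorporation_null(p_16_0: float) -> dict[str, float]:
    """Expected chain-composition fractions under random incorporation.

    With 16:0 precursor fraction ``p`` and independent choice of each of the
    two chains: DP = p^2, DO = (1-p)^2, PO = 2 p (1-p).
    """
    if not 0 <= p_16_0 <= 1:
        raise ValueError("p_16_0 must be in [0, 1]")
    p = p_16_0
    return {"DP": p * p, "DO": (1 - p) * (1 - p), "PO": 2 * p * (1 - p)}


def chain_composition_fractions(
    end_product_concentrations: dict[str, float],
    species: dict[str, LipidSpecies] | None = None,
    p_16_0: float = 0.5,
) -> tuple[dict[str, float], dict[str, float]]:
    """Observed diacyl chain-composition fractions and the random null.

    ``end_product_concentrations`` maps species id to concentration (uM);
    concentrations are summed within the DP/DO/PO categories and normalized
    by the total.  Returns ``(observed, null)``, each summing to 1.
    """
    registry = species or DEFAULT_SPECIES
    totals = {"DP": 0.0, "DO": 0.0, "PO": 0.0}
    for sp_id, conc in end_product_concentrations.items():
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        sp = registry.get(sp_id)
        if sp is None:
            raise ValueError(f"unknown lipid species {sp_id!r}")
        cat = _chain_category(sp)
        if cat is not None:
            totals[cat] += conc
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total diacyl end-product concentration is zero")
    observed = {cat: val / grand for cat, val in totals.items()}
    return observed, random_incorporation_null(p_16_0)


def conversion_yield(
    product_concentrations: dict[str, float],
    precursor_acyl_coa_uM: float,
    species: dict[str, LipidSpecies] | None = None,
) -> float:
    """Acyl-CoA conversion yield in percent.

    Each product consumes ``n_acyl_chains`` precursor molecules, so the
    yield is 100 * sum(conc_i * n_chains_i) / [acyl-CoA]_0.  20 uM of
    diacyl end products from 100 uM acyl-CoA is a 40% yield.
    """
    if precursor_acyl_coa_uM <= 0:
        raise ValueError("precursor concentration must be positive")
    registry = species or DEFAULT_SPECIES
    consumed = 0.0
    for sp_id, conc in product_concentrations.items():
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        sp = registry.get(sp_id)
        if sp is None:
            raise ValueError(f"unknown lipid species {sp_id!r}")
        consumed += conc * sp.n_acyl_chains
    return 100.0 * consumed / precursor_acyl_coa_uM


def quantify_samples(
    calibration: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """End-to-end quantification of a sample peak table.

    Averages duplicate injections, fits one calibration line per species
    present in both tables, and back-calculates concentrations.  Returns a
    tidy table (sample_id, transition_id, counts, concentration_uM, clamped,
    slope, intercept, r_squared).
    """
    avg = average_injections(samples)
    out_rows = []
    for sp_id in sorted(avg["transition_id"].unique()):
        fit = fit_calibration(calibration, sp_id)
        rows = avg[avg["transition_id"] == sp_id]
        conc, clamped = counts_to_concentration(rows["counts"].to_numpy(), fit)
        for (_, row), c, cl in zip(rows.iterrows(), np.atleast_1d(conc), np.atleast_1d(clamped)):
            out_rows.append(
                {
                    "sample_id": row["sample_id"],
                    "transition_id": sp_id,
                    "counts": row["counts"],
                    "concentration_uM": float(c),
                    "clamped": bool(cl),
                    "slope": fit.slope_counts_per_uM,
                    "intercept": fit.intercept_counts,
                    "r_squared": fit.r_squared,
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "sample_id",
            "transition_id",
            "counts",
            "concentration_uM",
            "clamped",
            "slope",
            "intercept",
            "r_squared",
        ],
    )
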