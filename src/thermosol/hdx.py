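"""Hydrogen-deuterium exchange (HDX-MS) comparative analysis.

Peptide-level deuterium uptake is normalized against undeuterated and
saturated-control centroid masses (%D), aggregated to per-residue site
profiles, differenced between condensate and monomer states (delta %D), and
compared across orthologs through a global sequence alignment with
shuffled-site permutation nulls.

Coverage follows standard HDX practice: the first residue of each peptide
(rapid back-exchange) and prolines (no amide proton) carry no signal and
are excluded from site coverage; both exclusions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteProfile",
    "DeltaProfile",
    "SiteAlignment",
    "percent_uptake",
    "site_profile",
    "delta_profile",
    "pairwise_align",
    "ortholog_site_correlation",
    "element_summary",
    "domain_summary",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def percent_uptake(
    mass_t: float,
    mass_undeut: float,
    mass_sat: float,
    tolerance: float = 0.0,
) -> float:
    """Proportional deuterium uptake of one peptide, in percent.

    ``100 * (mass_t - mass_undeut) / (mass_sat - mass_undeut)``, clipped to
    [0, 100].  Normalizing against the overnight saturated control removes
    back-exchange.  A centroid below the undeuterated mass by more than
    ``tolerance`` Da is flagged with a ``ValueError``.
    """
    if mass_sat <= mass_undeut:
        raise ValueError("mass_sat must exceed mass_undeut")
    if mass_t < mass_undeut - tolerance:
        raise ValueError(
            f"mass_t {mass_t} below undeuterated mass {mass_undeut} "
            f"beyond tolerance {tolerance}"
        )
    frac = (mass_t - mass_undeut) / (mass_sat - mass_undeut)
    return float(np.clip(100.0 * frac, 0.0, 100.0))


@dataclass
class SiteProfile:
    """Per-residue %D for one protein/state/timepoint.

    ``values`` has one slot per residue (index 0 = residue 1); uncovered
    residues are NaN, so the coverage mask is explicit in the data.
    """

    protein: str
    state: str
    timepoint: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        covered = self.values[~np.isnan(self.values)]
        if covered.size and (covered.min() < 0 or covered.max() > 100):
            raise ValueError("site %D values must lie in [0, 100]")

    @property
    def coverage(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DeltaProfile:
    """Per-residue condensate-minus-monomer delta %D.

    Positive values mean more exchange in the condensate (local unfolding
    or increased solvent exposure); negative values mean new protection.
    Missing wherever either state is uncovered.
    """

    protein: str
    timepoint: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)

    @property
    def coverage(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return self.values.size


def _covered_sites(
    start: int,
    end: int,
    sequence: str,
    exclude_first: bool,
    exclude_prolines: bool,
) -> list[int]:
    """1-based residue indices of a peptide span that carry exchange signal."""
    first = start + 1 if exclude_first else start
    sites = []
    for pos in range(first, end + 1):
        if exclude_prolines and sequence[pos - 1] == "P":
            continue
        sites.append(pos)
    return sites


def site_profile(
    peptides: pd.DataFrame,
    sequence: str,
    exclude_first: bool = True,
    exclude_prolines: bool = True,
    min_confidence: str | None = None,
) -> SiteProfile:
    """Aggregate peptide %D to a per-residue profile.

    Each residue's value is the unweighted mean %D over every peptide
    covering it; residues covered by no peptide are missing.  All peptides
    must share one protein, state and timepoint.  Columns: ``protein``,
    ``state``, ``start``, ``end``, ``timepoint_s`` and either ``percent_d``
    or the three centroid-mass columns (``mass_t``, ``mass_undeut``,
    ``mass_sat``).  ``min_confidence`` keeps only rows whose ``confidence``
    column matches (e.g. {"Medium", "High"} when set to "Medium").
    """
    if peptides.empty:
        raise ValueError("no peptides supplied")
    for col in ("protein", "state", "start", "end", "timepoint_s"):
        if col not in peptides.columns:
            raise ValueError(f"peptide table missing column {col!r}")
    if min_confidence is not None:
        order = {"Low": 0, "Medium": 1, "High": 2}
        floor = order[min_confidence]
        peptides = peptides[
            peptides["confidence"].map(order).fillna(-1) >= floor
        ]
        if peptides.empty:
            raise ValueError("no peptides at or above requested confidence")
    for col in ("protein", "state", "timepoint_s"):
        if peptides[col].nunique() != 1:
            raise ValueError(f"peptides must share a single {col}")
    length = len(sequence)
    if (peptides["end"] > length).any() or (peptides["start"] < 1).any():
        raise ValueError("peptide span outside the protein sequence")

    if "percent_d" in peptides.columns:
        pct = peptides["percent_d"].to_numpy(float)
    else:
        pct = np.array(
            [
                percent_uptake(r.mass_t, r.mass_undeut, r.mass_sat)
                for r in peptides.itertuples()
            ]
        )

    total = np.zeros(length)
    count = np.zeros(length, int)
    for (start, end), p in zip(
        peptides[["start", "end"]].itertuples(index=False), pct
    ):
        for pos in _covered_sites(
            int(start), int(end), sequence, exclude_first, exclude_prolines
        ):
            total[pos - 1] += p
            count[pos - 1] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SiteProfile(
        protein=str(peptides["protein"].iloc[0]),
        state=str(peptides["state"].iloc[0]),
        timepoint=float(peptides["timepoint_s"].iloc[0]),
        values=values,
    )


def delta_profile(cond: SiteProfile, mono: SiteProfile) -> DeltaProfile:
    """Condensate-minus-monomer per-residue difference profile."""
    if cond.protein != mono.protein:
        raise ValueError("profiles are for different proteins")
    if cond.timepoint != mono.timepoint:
        raise ValueError("profiles are at different timepoints")
    if len(cond) != len(mono):
        raise ValueError("profiles have different lengths")
    return DeltaProfile(
        protein=cond.protein,
        timepoint=cond.timepoint,
        values=cond.values - mono.values,
    )


@dataclass
class SiteAlignment:
    """Residue-index mapping between two aligned protein sequences.

    ``pairs`` holds (i, j) 1-based residue indices matched in non-gap
    columns, strictly increasing in both proteins.  ``score`` is the
    alignment score under the scoring scheme used.
    """

    id_a: str
    id_b: str
    pairs: list = field(default_factory=list)
    score: float = float("nan")

    def __post_init__(self):
        last_i = last_j = 0
        for i, j in self.pairs:
            if i <= last_i or j <= last_j:
                raise ValueError("aligned indices must be strictly increasing")
            last_i, last_j = i, j


def pairwise_align(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    matrix: str = "BLOSUM62",
) -> SiteAlignment:
    """Global pairwise protein alignment (Needleman-Wunsch, affine gaps).

    BLOSUM62 substitution scores by default; the first optimal alignment is
    taken, which fixes the tie-break deterministically.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, seq in ((id_a, seq_a), (id_b, seq_b)):
        if not seq:
            raise ValueError(f"empty sequence for {name}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid characters in {name}: {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for k in range(a_end - a_start):
            pairs.append((a_start + k + 1, b_start + k + 1))
    return SiteAlignment(id_a=id_a, id_b=id_b, pairs=pairs, score=float(aln.score))


def ortholog_site_correlation(
    profile_a,
    profile_b,
    aln: SiteAlignment,
    n_shuffles: int = 1000,
    seed: int = 0,
    min_overlap: int = 20,
) -> tuple[float, np.ndarray]:
    """Site-by-site Pearson correlation across orthologs, with shuffle null.

    Correlates two site (or delta) profiles over aligned, doubly covered,
    non-gap columns; the null distribution comes from ``n_shuffles`` seeded
    random permutations of one profile's columns.  Works identically for %D
    and delta %D profiles.
    """
    va, vb = profile_a.values, profile_b.values
    idx_a = np.array([i - 1 for i, _ in aln.pairs], int)
    idx_b = np.array([j - 1 for _, j in aln.pairs], int)
    if idx_a.size == 0:
        raise ValueError("alignment has no matched columns")
    x = va[idx_a]
    y = vb[idx_b]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_overlap:
        raise ValueError(
            f"only {int(ok.sum())} jointly covered aligned columns "
            f"(need >= {min_overlap})"
        )
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance profile; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
    return r, null


def element_summary(
    profile: SiteProfile, ss_annotation
) -> pd.DataFrame:
    """Box statistics of site %D per secondary-structure element.

    ``ss_annotation`` assigns each residue a label from
    {loop, helix, strand}; covered residues are summarized per element with
    standard box statistics (quartiles, median, 1.5*IQR whiskers, outlier
    count).
    """
    labels = np.asarray(ss_annotation, object)
    if labels.size != len(profile):
        raise ValueError("annotation length does not match profile")
    known = {"loop", "helix", "strand"}
    unknown = set(labels.tolist()) - known
    if unknown:
        raise ValueError(f"unknown element labels: {sorted(unknown)}")
    rows = []
    for element in sorted(known):
        vals = profile.values[(labels == element) & profile.coverage]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_w = vals[vals >= q1 - 1.5 * iqr].min()
        hi_w = vals[vals <= q3 + 1.5 * iqr].max()
        n_out = int(((vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)).sum())
        rows.append(
            {
                "element": element,
                "n": vals.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": lo_w,
                "whisker_high": hi_w,
                "n_outliers": n_out,
            }
        )
    return pd.DataFrame(rows).set_index("element")


def domain_summary(delta: DeltaProfile, domains: dict) -> pd.DataFrame:
    """Mean +/- SE of delta %D over covered residues for named domains.

    ``domains`` maps a domain name to a 1-based inclusive (start, end)
    residue range.
    """
    rows = []
    for name, (start, end) in domains.items():
        if start < 1 or end > len(delta) or start > end:
            raise ValueError(f"domain {name!r} range ({start}, {end}) out of bounds")
        vals = delta.values[start - 1 : end]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"domain {name!r} has no covered residues")
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        rows.append(
            {"domain": name, "mean": float(vals.mean()), "se": se, "n": int(vals.size)}
        )
    return pd.DataFrame(rows).set_index("domain")
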