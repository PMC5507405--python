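"""Signed pathway -> gene regulatory network from perturbation fold-change tables.

Six-hour pathway stimulation/inhibition experiments yield per-gene fold
changes (treated/control) with p-values.  A gene is called regulated by a
pathway when the response clears both a fold-change threshold (|log ratio|
>= log threshold) and a significance threshold.  Calls from stimulated and
inhibited conditions are merged (an inhibited-condition response implies the
opposite regulation sign); contradictory evidence yields no edge.  The gene
network is then collapsed onto five pathway species -- BMP, WNT,
WNT inhibitor, BMP inhibitor, FGF -- producing the signed interaction matrix
that feeds linear stability analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PATHWAYS = ("BMP", "FGF", "WNT")
SPECIES = ("BMP", "WNT", "WNT_inhibitor", "BMP_inhibitor", "FGF")


class InvalidRecordError(ValueError):
    pass


class InvalidGroupingError(ValueError):
    pass


@dataclass(frozen=True)
class FoldChangeRecord:
    """One gene's response to one pathway perturbation condition."""

    gene: str
    pathway: str
    direction: str  # "stimulated" or "inhibited"
    fold_change: float  # treated/control ratio, > 0
    p_value: float
    dermal_fraction: float | None = None  # metadata only; does not gate edges

    def __post_init__(self):
        if self.fold_change <= 0:
            raise InvalidRecordError(
                f"{self.gene}: fold_change must be positive, got {self.fold_change}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidRecordError(f"{self.gene}: p_value outside [0, 1]")
        if self.direction not in ("stimulated", "inhibited"):
            raise InvalidRecordError(f"unknown direction {self.direction!r}")


@dataclass
class GeneNetwork:
    """Signed (pathway, gene) edges plus the thresholds that produced them."""

    edges: dict[tuple[str, str], int]  # (pathway, gene) -> +1 / -1
    fc_threshold: float
    alpha: float
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    conflicts: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "edges": [
                {"pathway": p, "gene": g, "sign": s, "evidence": self.provenance.get((p, g), [])}
                for (p, g), s in sorted(self.edges.items())
            ],
            "conflicts": [list(c) for c in self.conflicts],
        }
        return json.dumps(payload, indent=2)


class SpeciesGrouping:
    """Mapping gene -> one of the five pathway species."""

    def __init__(self, mapping: dict[str, str]):
        for gene, sp in mapping.items():
            if sp not in SPECIES:
                raise InvalidGroupingError(f"unknown species {sp!r} for gene {gene}")
        self.mapping = dict(mapping)

    @classmethod
    def from_lists(cls, lists: dict[str, list[str]]) -> "SpeciesGrouping":
        mapping: dict[str, str] = {}
        for sp, genes in lists.items():
            for g in genes:
                if g in mapping:
                    raise InvalidGroupingError(f"gene {g} assigned to two species")
                mapping[g] = sp
        return cls(mapping)

    def __getitem__(self, gene: str) -> str:
        return self.mapping[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping


def default_grouping() -> SpeciesGrouping:
    """The main-text grouping of the 15 regulated candidates into 5 species."""
    return SpeciesGrouping.from_lists(
        {
            "BMP": ["Bmp2", "Bmp4", "Rgma"],
            "WNT": ["Wnt9a", "Ror2", "Fzd10"],
            "WNT_inhibitor": ["Dkk1", "Dkk4"],
            "BMP_inhibitor": ["Bambi", "Nog"],
            "FGF": ["Fgf20"],
        }
    )


class SignedInteractionMatrix:
    """5x5 matrix with entries in {-1, 0, +1}; M[i, j] = effect of species j on species i."""

    def __init__(self, entries, species=SPECIES, provenance=None):
        M = np.asarray(entries, dtype=int)
        if M.shape != (len(species), len(species)):
            raise ValueError(f"matrix shape {M.shape} does not match species list")
        if not np.isin(M, (-1, 0, 1)).all():
            raise ValueError("entries must be in {-1, 0, +1}")
        self.species = tuple(species)
        self.M = M
        self.provenance = provenance or {}

    def __getitem__(self, key):
        return self.M[key]

    def index(self, sp: str) -> int:
        return self.species.index(sp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SignedInteractionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.values, species=tuple(df.index))


def default_matrix() -> SignedInteractionMatrix:
    """Sign structure of the BMP/FGF/WNT interaction network.

    Partial reconstruction from the named regulations: WNT stimulates the
    placode suite (*Bmp2*, *Dkk4*/*Dkk1*, *Fgf20*); BMP opposes that suite
    and additionally induces its own inhibitors (*Bambi*, *Nog*); FGF
    represses the epithelial WNT targets including its own ligand *Fgf20*;
    each dedicated inhibitor species suppresses its pathway.  Entries the
    text does not determine are zero.
    """
    sp = SPECIES
    M = np.zeros((5, 5), dtype=int)

    def put(target, source, sign):
        M[sp.index(target), sp.index(source)] = sign

    # WNT stimulates the primordium gene suite
    put("BMP", "WNT", +1)            # Bmp2 up
    put("WNT_inhibitor", "WNT", +1)  # Dkk4, Dkk1 up
    put("FGF", "WNT", +1)            # Fgf20 up
    # BMP opposes the suite and induces its own inhibitors
    put("WNT", "BMP", -1)
    put("BMP", "BMP", -1)            # Bmp2 down under BMP
    put("WNT_inhibitor", "BMP", -1)
    put("FGF", "BMP", -1)
    put("BMP_inhibitor", "BMP", +1)  # Bambi, Nog up
    # FGF represses the epithelial WNT-activated targets
    put("BMP", "FGF", -1)
    put("WNT_inhibitor", "FGF", -1)
    put("FGF", "FGF", -1)            # Fgf20 down under FGF
    # dedicated inhibitor arms
    put("WNT", "WNT_inhibitor", -1)
    put("BMP", "BMP_inhibitor", -1)
    return SignedInteractionMatrix(M)


def _implied_sign(rec: FoldChangeRecord, fc_threshold: float, alpha: float) -> int:
    """Regulation sign implied by one record, or 0 if below threshold."""
    if rec.p_value >= alpha:
        return 0
    if rec.fold_change >= fc_threshold:
        observed = +1
    elif rec.fold_change <= 1.0 / fc_threshold:
        observed = -1
    else:
        return 0
    return observed if rec.direction == "stimulated" else -observed


def derive_gene_network(
    records: list[FoldChangeRecord],
    fc_threshold: float = 1.8,
    alpha: float = 0.05,
    pathways: tuple[str, ...] = PATHWAYS,
) -> GeneNetwork:
    """Call signed (pathway, gene) edges from fold-change records.

    An edge requires p < alpha and ratio >= fc_threshold (up) or
    <= 1/fc_threshold (down); inhibited-condition responses imply the
    opposite regulation sign.  If the two conditions imply contradictory
    signs for a pair, no edge is recorded and a warning is emitted.
    """
    if not records:
        raise InvalidRecordError("empty record list")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    calls: dict[tuple[str, str], set[int]] = {}
    evidence: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        if rec.pathway not in pathways:
            raise InvalidRecordError(f"unknown pathway label {rec.pathway!r}")
        s = _implied_sign(rec, fc_threshold, alpha)
        if s == 0:
            continue
        key = (rec.pathway, rec.gene)
        calls.setdefault(key, set()).add(s)
        evidence.setdefault(key, []).append(
            f"{rec.direction}: FC={rec.fold_change:.3g}, p={rec.p_value:.3g}"
        )
    edges: dict[tuple[str, str], int] = {}
    conflicts: list[tuple[str, str]] = []
    for key, signs in calls.items():
        if len(signs) > 1:
            conflicts.append(key)
            warnings.warn(
                f"conflicting regulation signs for {key}; edge dropped", stacklevel=2
            )
            continue
        edges[key] = signs.pop()
    return GeneNetwork(
        edges=edges,
        fc_threshold=fc_threshold,
        alpha=alpha,
        provenance={k: evidence[k] for k in edges},
        conflicts=conflicts,
    )


def records_from_frame(df: pd.DataFrame) -> list[FoldChangeRecord]:
    """Build records from a table with columns gene,pathway,direction,fold_change,p_value[,dermal_fraction]."""
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            FoldChangeRecord(
                gene=str(row.gene),
                pathway=str(row.pathway),
                direction=str(row.direction),
                fold_change=float(row.fold_change),
                p_value=float(row.p_value),
                dermal_fraction=float(row.dermal_fraction)
                if hasattr(row, "dermal_fraction") and pd.notna(row.dermal_fraction)
                else None,
            )
        )
    return recs


def collapse_to_species(
    network: GeneNetwork,
    grouping: SpeciesGrouping,
    species: tuple[str, ...] = SPECIES,
    source_species: tuple[str, ...] | None = None,
) -> SignedInteractionMatrix:
    """Consensus sign of edges from each pathway onto the genes of each species.

    Cells whose contributing genes disagree in sign are set to 0 with a
    warning; cell provenance records the contributing genes.
    """
    src = source_species if source_species is not None else species
    n = len(species)
    M = np.zeros((n, n), dtype=int)
    provenance: dict[tuple[str, str], list[str]] = {}
    ungrouped = sorted({g for (_, g) in network.edges if g not in grouping})
    if ungrouped:
        warnings.warn(f"ungrouped genes ignored in collapse: {ungrouped}", stacklevel=2)
    for (pathway, gene), sign in network.edges.items():
        if gene not in grouping or pathway not in src:
            continue
        i = species.index(grouping[gene])
        j = species.index(pathway)
        provenance.setdefault((species[i], pathway), []).append(f"{gene}:{sign:+d}")
        if M[i, j] == 0:
            M[i, j] = sign
        elif M[i, j] != sign:
            warnings.warn(
                f"conflicting gene-level signs in cell ({species[i]}, {pathway}); set to 0",
                stacklevel=2,
            )
            M[i, j] = 0
    return SignedInteractionMatrix(M, species=species, provenance=provenance)


# Dedicated inhibitor species per pathway, for the self-inhibition report.
_INHIBITOR_OF = {"WNT": "WNT_inhibitor", "BMP": "BMP_inhibitor"}


def validate_self_inhibition(matrix: SignedInteractionMatrix) -> dict[str, dict]:
    """Advisory report: does each species carry a net negative self-loop?

    Checks the diagonal entry and, where the species has a dedicated
    inhibitor, the two-step loop species -> inhibitor -> species (negative
    when the sign product of the two edges is -1).
    """
    report: dict[str, dict] = {}
    for sp in matrix.species:
        i = matrix.index(sp)
        direct = int(matrix[i, i])
        via_inhibitor = 0
        inh = _INHIBITOR_OF.get(sp)
        if inh is not None and inh in matrix.species:
            k = matrix.index(inh)
            via_inhibitor = int(matrix[k, i] * matrix[i, k])
        report[sp] = {
            "direct": direct,
            "via_inhibitor": via_inhibitor,
            "self_inhibiting": direct < 0 or via_inhibitor < 0,
        }
    return report


def ttest_fold_changes(
    treated: np.ndarray, control: np.ndarray
) -> tuple[float, float]:
    """Helper: fold change and Welch t-test p-value from replicate expression values."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if (treated <= 0).any() or (control <= 0).any():
        raise InvalidRecordError("expression values must be positive")
    fc = treated.mean() / control.mean()
    _, p = stats.ttest_ind(treated, control, equal_var=False)
    return float(fc), float(p)
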