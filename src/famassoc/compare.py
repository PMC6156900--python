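"""Top-k comparison of the three modeling options.

Significance is defined by top-k ranking (smallest p-values, ties broken by
marker index), mirroring the "top 100" / "top 20" protocol.  The module
computes seven-region Venn overlaps between the representative (A), kinship
(B) and independence (C) top-k sets, truth recovery and false discovery
rates, a nestedness diagnostic (ideally the significant sets would satisfy
representative ⊆ kinship ⊆ independence in expectation — in practice they
do not, which is the point of the diagnostic), and the hybrid strategy that
intersects the independence and representative sets.  ``run_study`` wires
the whole pipeline over replicate simulations and representative re-draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .lmm import fit_all
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "TopKSet",
    "VennSummary",
    "RecoveryEntry",
    "NestednessReport",
    "StudyReport",
    "top_k",
    "venn_counts",
    "recovery",
    "hybrid_set",
    "nestedness_report",
    "run_study",
    "derive_seed",
]

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")
#: Venn set convention, fixed throughout: A=representative, B=kinship,
#: C=independence.
VENN_SETS = {"A": "representative", "B": "kinship", "C": "independence"}


@dataclass(frozen=True)
class TopKSet:
    option: str
    run_id: int
    k: int
    marker_ids: tuple[str, ...]  # ascending p, ties by ascending marker index

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))

    def as_set(self) -> frozenset[str]:
        return frozenset(self.marker_ids)


@dataclass(frozen=True)
class VennSummary:
    """Counts of the 7 mutually exclusive regions of a 3-set Venn diagram."""

    region_counts: dict[str, int]
    run_id: int = 0

    def __post_init__(self) -> None:
        missing = set(VENN_REGIONS) - set(self.region_counts)
        if missing:
            raise ValueError(f"missing Venn regions: {sorted(missing)}")

    def set_total(self, which: str) -> int:
        """Total size of set ``which`` in {A, B, C} (sum of its regions)."""
        return sum(
            count for region, count in self.region_counts.items() if which in region
        )


@dataclass(frozen=True)
class RecoveryEntry:
    option: str
    size: int
    true_positives: int
    fdr: float


@dataclass(frozen=True)
class NestednessReport:
    rep_minus_kin: int
    kin_minus_indep: int
    rep_subset_kin: bool
    kin_subset_indep: bool


def top_k(results: pd.DataFrame, k: int, run_id: int = 0) -> TopKSet:
    """Top-``k`` markers by ascending p-value, ties by ascending table index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    options = results["option"].unique()
    if len(options) != 1:
        raise ValueError(f"expected a single option per table, got {list(options)}")
    p = results["p_value"].to_numpy()
    order = np.lexsort((np.arange(len(p)), p))[: min(k, len(p))]
    ids = tuple(results["marker_id"].to_numpy()[order])
    return TopKSet(str(options[0]), run_id, k, ids)


def venn_counts(
    A: Iterable[str], B: Iterable[str], C: Iterable[str], run_id: int = 0
) -> VennSummary:
    """Counts of the 7 exclusive regions of sets A, B, C."""
    A, B, C = set(A), set(B), set(C)
    counts = {
        "ABC": len(A & B & C),
        "AB": len((A & B) - C),
        "AC": len((A & C) - B),
        "BC": len((B & C) - A),
        "A": len(A - B - C),
        "B": len(B - A - C),
        "C": len(C - A - B),
    }
    return VennSummary(counts, run_id)


def recovery(topk: TopKSet, truth: Iterable[str]) -> RecoveryEntry:
    """Truth overlap and false discovery rate of one top-k set."""
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    size = len(topk.marker_ids)
    tp = len(topk.as_set() & truth)
    return RecoveryEntry(topk.option, size, tp, (size - tp) / size if size else 0.0)


def _recovery_of_set(ids: frozenset[str], truth: set[str], label: str) -> RecoveryEntry:
    size = len(ids)
    tp = len(ids & truth)
    return RecoveryEntry(label, size, tp, (size - tp) / size if size else 0.0)


def hybrid_set(indep_topk: TopKSet, rep_topk: TopKSet) -> frozenset[str]:
    """The hybrid strategy: markers found by both the independence and the
    representative options (set intersection of their top-k sets)."""
    return indep_topk.as_set() & rep_topk.as_set()


def nestedness_report(
    rep: TopKSet, kin: TopKSet, indep: TopKSet
) -> NestednessReport:
    """How far the sets are from the ideal nesting rep ⊆ kin ⊆ indep.

    Reports escape counts and subset flags; never asserts nestedness, which
    typically fails in finite samples.
    """
    if not (rep.k == kin.k == indep.k):
        raise ValueError("nestedness_report requires equal k across options")
    r, g, b = rep.as_set(), kin.as_set(), indep.as_set()
    return NestednessReport(
        rep_minus_kin=len(r - g),
        kin_minus_indep=len(g - b),
        rep_subset_kin=r <= g,
        kin_subset_indep=g <= b,
    )


def derive_seed(*parts: int) -> int:
    """Stable sub-2^31 seed derived from an integer tuple (splittable)."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class StudyReport:
    """Per-run and aggregated results of a replicated comparison study."""

    venn_runs: pd.DataFrame = field(repr=False)
    recovery_runs: pd.DataFrame = field(repr=False)
    nestedness_runs: pd.DataFrame = field(repr=False)
    k: int
    config: SimulationConfig
    seeds: dict = field(repr=False)

    def aggregate_venn(self, by: Optional[str] = None) -> pd.DataFrame:
        """Mean and sample SD (ddof=1) of each Venn region across runs.

        ``by`` may be "replicate" or "draw" to aggregate along one axis
        only; default pools all runs.
        """
        cols = list(VENN_REGIONS)
        if by is None:
            agg = self.venn_runs[cols].agg(["mean", "std"]).T
            agg.index.name = "region"
            return agg.reset_index()
        out = self.venn_runs.groupby(by)[cols].agg(["mean", "std"])
        return out

    def aggregate_recovery(self) -> pd.DataFrame:
        """Mean and sample SD of size / true positives / FDR per option."""
        out = (
            self.recovery_runs.groupby("option")[["size", "true_positives", "fdr"]]
            .agg(["mean", "std"])
        )
        return out

    def mean_true_positives(self) -> dict[str, float]:
        means = self.recovery_runs.groupby("option")["true_positives"].mean()
        return means.to_dict()

    def mean_fdr(self) -> dict[str, float]:
        return self.recovery_runs.groupby("option")["fdr"].mean().to_dict()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.venn_runs.to_csv(outdir / "venn_runs.tsv", sep="\t", index=False)
        self.recovery_runs.to_csv(outdir / "recovery_runs.tsv", sep="\t", index=False)
        self.nestedness_runs.to_csv(
            outdir / "nestedness_runs.tsv", sep="\t", index=False
        )
        self.aggregate_venn().to_csv(
            outdir / "venn_aggregate.tsv", sep="\t", index=False
        )
        self.aggregate_recovery().to_csv(outdir / "recovery_aggregate.tsv", sep="\t")
        (outdir / "summary.txt").write_text(self.summary_text())

    def summary_text(self) -> str:
        """Plain-text summary: average region counts ± SD, plus recovery."""
        lines = [
            f"Comparison study: k={self.k}, "
            f"{self.venn_runs['replicate'].nunique()} replicates x "
            f"{self.venn_runs['draw'].nunique()} representative draws",
            "Venn sets: A=representative, B=kinship, C=independence",
            "",
            "Average region counts +/- SD:",
        ]
        agg = self.aggregate_venn()
        for _, row in agg.iterrows():
            sd = 0.0 if np.isnan(row["std"]) else row["std"]
            lines.append(f"  {row['region']:>3}: {row['mean']:6.2f} +/- {sd:.2f}")
        lines.append("")
        lines.append("Truth recovery (mean true positives, mean FDR):")
        tp, fdr = self.mean_true_positives(), self.mean_fdr()
        for opt in ("representative", "kinship", "independence", "hybrid"):
            if opt in tp:
                lines.append(f"  {opt:>14}: TP={tp[opt]:.2f}  FDR={fdr[opt]:.3f}")
        return "\n".join(lines) + "\n"


def run_study(
    config: SimulationConfig,
    n_replicates: int = 3,
    n_representative_draws: int = 5,
    k: int = 20,
    vc_method: str = "reml",
) -> StudyReport:
    """Replicate the simulation comparison end to end.

    For each replicate: simulate a dataset (seed derived from
    ``config.seed`` and the replicate index), fit the kinship and
    independence options once, and the representative option once per
    representative draw; take top-k sets, Venn region counts, truth
    recovery for each option and for the hybrid intersection.  One run =
    (replicate, draw); kinship and independence results repeat across draws
    within a replicate, as in the original protocol where only the
    representative sets vary.
    """
    if n_replicates < 1 or n_representative_draws < 1:
        raise ValueError("n_replicates and n_representative_draws must be >= 1")
    venn_rows, rec_rows, nest_rows = [], [], []
    seeds: dict = {"config_seed": config.seed, "replicates": {}}
    run_id = 0
    for r in range(n_replicates):
        sim_seed = derive_seed(config.seed, r)
        seeds["replicates"][r] = {"simulation": sim_seed, "draws": {}}
        ds = simulate_dataset(config.replace(seed=sim_seed))
        truth_ids = set(ds.causal_ids)
        kin_tab = fit_all(ds, "kinship", vc_method=vc_method)
        ind_tab = fit_all(ds, "independence")
        kin_top = top_k(kin_tab, k, run_id)
        ind_top = top_k(ind_tab, k, run_id)
        for d in range(n_representative_draws):
            rep_seed = derive_seed(config.seed, r, 1000 + d)
            seeds["replicates"][r]["draws"][d] = rep_seed
            rep_tab = fit_all(ds, "representative", representative_seed=rep_seed)
            rep_top = top_k(rep_tab, k, run_id)
            venn = venn_counts(
                rep_top.as_set(), kin_top.as_set(), ind_top.as_set(), run_id
            )
            venn_rows.append(
                {"run_id": run_id, "replicate": r, "draw": d, **venn.region_counts}
            )
            hybrid = hybrid_set(ind_top, rep_top)
            for entry in (
                recovery(rep_top, truth_ids),
                recovery(kin_top, truth_ids),
                recovery(ind_top, truth_ids),
                _recovery_of_set(hybrid, truth_ids, "hybrid"),
            ):
                rec_rows.append(
                    {
                        "run_id": run_id,
                        "replicate": r,
                        "draw": d,
                        "option": entry.option,
                        "size": entry.size,
                        "true_positives": entry.true_positives,
                        "fdr": entry.fdr,
                    }
                )
            nest = nestedness_report(rep_top, kin_top, ind_top)
            nest_rows.append(
                {
                    "run_id": run_id,
                    "replicate": r,
                    "draw": d,
                    "rep_minus_kin": nest.rep_minus_kin,
                    "kin_minus_indep": nest.kin_minus_indep,
                    "rep_subset_kin": nest.rep_subset_kin,
                    "kin_subset_indep": nest.kin_subset_indep,
                }
            )
            run_id += 1
    return StudyReport(
        venn_runs=pd.DataFrame(venn_rows),
        recovery_runs=pd.DataFrame(rec_rows),
        nestedness_runs=pd.DataFrame(nest_rows),
        k=k,
        config=config,
        seeds=seeds,
    )
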