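"""End-to-end analysis: tree + trait table + SSC states -> report bundle.

Reproduces the full result surface of a Rensch's-rule study on a clade
with male/female body lengths and optional genital metrics:

* allometry table: RMA slopes of male on female log10 size per taxon
  group, from independent contrasts (through origin) and from raw data,
* contrast correlations of rSSD with each sex's size and with genital
  complexity metrics,
* Blomberg's K phylogenetic-signal table,
* per-branch change tables with the 5% qualitative coding, their
  cross-tabulation, the single-sex binomial sign test, and the
  male-female rate-difference regressions,
* Fitch parsimony gain/loss reconstruction of binary secondary sexual
  characters, exported as an annotated Newick string.

All randomized steps (polytomy resolution, bootstrap, permutations)
consume independent named sub-seeds derived from one master seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import branch_change as bc
from .ancestral import asr_bm, asr_parsimony
from .comparative import blomberg_k, contrast_correlation, rma
from .trees import Phylogeny, read_tree, resolve_polytomies

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "subseed"]

logger = logging.getLogger(__name__)


def subseed(master: int, name: str) -> int:
    """Stable named sub-seed (< 2^31) derived from a master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class AnalysisConfig:
    """Inputs and knobs for one full analysis run.

    ``tree`` / ``traits`` may be in-memory objects or file paths (Newick;
    delimited text with a ``species`` column plus ``male_length`` and
    ``female_length`` in mm).  ``groups`` maps group names to tip subsets
    (taxonomy is input, not computation); the first group drives the
    branch-change and parsimony sections.  Thresholds are fractions in
    (0, 1).
    """

    tree: Phylogeny | str
    traits: pd.DataFrame | str
    ssc: dict[str, dict[str, int]] = field(default_factory=dict)
    groups: dict[str, list[str]] | None = None
    size_threshold: float = 0.05
    ssd_threshold_fraction: float = 0.05
    n_boot: int = 1999
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self):
        for thr in (self.size_threshold, self.ssd_threshold_fraction):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class AnalysisReport:
    seed: int
    allometry: pd.DataFrame          # RMA slopes per group x {contrasts, raw}
    ssd_correlations: pd.DataFrame   # rSSD vs sizes and genital metrics
    k_table: pd.DataFrame
    branch_table: pd.DataFrame
    codes_table: pd.DataFrame
    crosstab_all: pd.DataFrame
    crosstab_over5: pd.DataFrame
    n_male_only: int
    n_female_only: int
    binomial_p: float | None
    rate_regressions: pd.DataFrame
    parsimony: pd.DataFrame
    annotated_trees: dict[str, str]

    def write(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "allometry.tsv": self.allometry,
            "ssd_correlations.tsv": self.ssd_correlations,
            "k_table.tsv": self.k_table,
            "branch_changes.tsv": self.branch_table,
            "branch_codes.tsv": self.codes_table,
            "crosstab_all_changes.tsv": self.crosstab_all,
            "crosstab_over_5pct.tsv": self.crosstab_over5,
            "rate_regressions.tsv": self.rate_regressions,
            "parsimony.tsv": self.parsimony,
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        summary = pd.DataFrame(
            [
                {"quantity": "seed", "value": self.seed},
                {"quantity": "n_male_only_ssd_change", "value": self.n_male_only},
                {"quantity": "n_female_only_ssd_change", "value": self.n_female_only},
                {"quantity": "binomial_p", "value": self.binomial_p},
            ]
        )
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        for char, nwk in self.annotated_trees.items():
            (out / f"parsimony_{char}.nwk").write_text(nwk)


def _load_traits(traits) -> pd.DataFrame:
    if isinstance(traits, (str, Path)):
        df = pd.read_csv(traits, sep=None, engine="python")
    else:
        df = traits.copy()
    need = {"species", "male_length", "female_length"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"trait table lacks columns: {sorted(missing)}")
    df = df.set_index("species", drop=False)
    df["ssd"] = df.male_length - df.female_length
    df["rssd"] = df.male_length / df.female_length
    return df


def _subtree(tree: Phylogeny, tips: list[str]) -> Phylogeny:
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(tips)
    return Phylogeny(sub)


def _col(df: pd.DataFrame, column: str, tips: list[str]) -> dict[str, float]:
    return {t: float(df.loc[t, column]) for t in tips}


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the whole analysis; deterministic under a fixed master seed."""
    tree = config.tree if isinstance(config.tree, Phylogeny) else read_tree(config.tree)
    traits = _load_traits(config.traits)

    common = [t for t in tree.tip_labels if t in traits.index]
    if not common:
        raise ValueError("no overlap between tree tips and trait-table species")
    extra_tree = sorted(set(tree.tip_labels) - set(common))
    extra_traits = sorted(set(traits.index) - set(common))
    if extra_tree:
        logger.warning("pruning %d tree tips without trait data: %s", len(extra_tree), extra_tree)
    if extra_traits:
        logger.warning("ignoring %d trait rows not in the tree: %s", len(extra_traits), extra_traits)
    tree = _subtree(tree, common)
    tree = resolve_polytomies(tree, seed=subseed(config.seed, "polytomies"))

    groups = config.groups or {"all": common}
    genital_cols = [
        c for c in ("aedeagus_length", "perimeter", "fractal_dimension")
        if c in traits.columns and traits[c].notna().all()
    ]

    allom_rows, corr_rows, k_rows = [], [], []
    for gname, gtips in groups.items():
        gtips = [t for t in gtips if t in common]
        if len(gtips) < 4:
            raise ValueError(f"group {gname!r} has fewer than 4 usable tips")
        gtree = _subtree(tree, gtips)
        male = _col(traits, "male_length", gtips)
        female = _col(traits, "female_length", gtips)
        lm = {k: np.log10(v) for k, v in male.items()}
        lf = {k: np.log10(v) for k, v in female.items()}

        fit = contrast_correlation(
            gtree, lf, lm,
            seed=subseed(config.seed, f"rma-contrast-{gname}"),
            n_boot=config.n_boot,
        )
        allom_rows.append({"group": gname, "data": "contrasts", "n": fit.n,
                           "slope": fit.slope, "ci_low": fit.ci_low,
                           "ci_high": fit.ci_high, "r2": fit.r2, "p": fit.p})
        xs = np.array([lf[t] for t in gtips])
        ys = np.array([lm[t] for t in gtips])
        raw = rma(xs, ys, through_origin=False,
                  seed=subseed(config.seed, f"rma-raw-{gname}"), n_boot=config.n_boot)
        allom_rows.append({"group": gname, "data": "raw", "n": raw.n,
                           "slope": raw.slope, "ci_low": raw.ci_low,
                           "ci_high": raw.ci_high, "r2": raw.r2, "p": raw.p})

        rssd = _col(traits, "rssd", gtips)
        for tname, tvals in [("male_length", male), ("female_length", female)] + [
            (c, _col(traits, c, gtips)) for c in genital_cols
        ]:
            try:
                cfit = contrast_correlation(
                    gtree, tvals, rssd,
                    seed=subseed(config.seed, f"corr-{gname}-{tname}"),
                    n_boot=config.n_boot,
                )
                row = {"n": cfit.n, "r2": cfit.r2, "p": cfit.p}
            except ValueError as exc:  # constant trait: correlation undefined
                logger.warning("correlation %s/%s skipped: %s", gname, tname, exc)
                row = {"n": len(gtips) - 1, "r2": np.nan, "p": np.nan}
            corr_rows.append({"group": gname, "trait": tname, **row})

        for tname, tvals in [("rssd", rssd), ("male_length", male),
                             ("female_length", female)]:
            try:
                kr = blomberg_k(gtree, tvals, n_perm=config.n_perm,
                                seed=subseed(config.seed, f"k-{gname}-{tname}"))
                k, p = kr.k, kr.p
            except ValueError as exc:  # constant trait: K undefined
                logger.warning("K %s/%s skipped: %s", gname, tname, exc)
                k, p = np.nan, np.nan
            k_rows.append({"group": gname, "trait": tname, "k": k, "p": p,
                           "n_perm": config.n_perm})

    # branch-change section on the first group's tree
    first = next(iter(groups))
    gtips = [t for t in groups[first] if t in common]
    gtree = _subtree(tree, gtips)
    asr_m = asr_bm(gtree, _col(traits, "male_length", gtips), trait="male_length")
    asr_f = asr_bm(gtree, _col(traits, "female_length", gtips), trait="female_length")
    rec_m = bc.branch_changes(gtree, asr_m)
    rec_f = bc.branch_changes(gtree, asr_f)
    ssd_range = bc.ssd_range_from_reconstructions(asr_m, asr_f)
    codes5 = bc.code_branches(rec_m, rec_f, ssd_range,
                              size_threshold=config.size_threshold,
                              ssd_threshold_fraction=config.ssd_threshold_fraction)
    codes_all = bc.code_branches(rec_m, rec_f, ssd_range, all_changes=True)
    n_m, n_f = bc.single_sex_ssd_counts(codes5)
    binom_p = bc.sign_binomial_test(n_m, n_f) if (n_m + n_f) else None

    branch_table = pd.DataFrame(
        [vars(r) for r in rec_m] + [vars(r) for r in rec_f]
    )
    codes_table = pd.DataFrame(
        [
            {"branch": a.branch, "lm_all": a.code_male, "lf_all": a.code_female,
             "ssd_all": a.code_ssd, "lm_5": b.code_male, "lf_5": b.code_female,
             "ssd_5": b.code_ssd}
            for a, b in zip(codes_all, codes5)
        ]
    )
    rate_regs = pd.concat(
        [bc.rate_difference_regression(rec_m, rec_f, metric=m)
         for m in ("darwins", "absolute")],
        ignore_index=True,
    )

    pars_rows, annotated = [], {}
    for char, states in config.ssc.items():
        pr = asr_parsimony(gtree, {t: states[t] for t in gtips}, character=char)
        pars_rows.append({"character": char, "length": pr.length,
                          "n_gains": len(pr.gains), "n_losses": len(pr.losses),
                          "gains": ";".join(pr.gains), "losses": ";".join(pr.losses),
                          "root_ambiguous": pr.root_ambiguous})
        annotated[char] = _annotated_newick(gtree, pr.states)
    parsimony = pd.DataFrame(
        pars_rows,
        columns=["character", "length", "n_gains", "n_losses", "gains",
                 "losses", "root_ambiguous"],
    )

    return AnalysisReport(
        seed=config.seed,
        allometry=pd.DataFrame(allom_rows),
        ssd_correlations=pd.DataFrame(corr_rows),
        k_table=pd.DataFrame(k_rows),
        branch_table=branch_table,
        codes_table=codes_table,
        crosstab_all=bc.crosstab(codes_all),
        crosstab_over5=bc.crosstab(codes5),
        n_male_only=n_m,
        n_female_only=n_f,
        binomial_p=binom_p,
        rate_regressions=rate_regs,
        parsimony=parsimony,
        annotated_trees=annotated,
    )


def _annotated_newick(tree: Phylogeny, states: dict[str, int]) -> str:
    """Newick with internal node labels ``<id>_state<state>``."""
    clone = tree.copy()
    for node in clone.preorder():
        if not node.is_leaf():
            node.label = f"{node._node_id}_state{states[node._node_id]}"
    return clone.to_newick()
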