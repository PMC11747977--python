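"""Inter-rater agreement: Cohen's kappa, permutation nulls, label
reconciliation, and seizure-level bifurcation-morphology resolution.

Two independent reviewers label every independent component (IC) of every
seizure, per side, as a clear transition or not, and — when clear — with a
bifurcation class.  Agreement is quantified with Cohen's kappa on the
binary clear/not labels and on the categorical class labels, against two
permutation nulls: shuffling one reviewer's labels overall, and shuffling
them only within each seizure (which preserves each reviewer's per-seizure
label counts and gives the harder chance level).  Only ICs on which both
reviewers assign the same class survive reconciliation; the seizure-level
class is then resolved from the agreed ICs by earliest transition anchor,
with the brain score breaking near-ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REVIEWER_COLUMNS = ("patient_id", "seizure_id", "ic_index", "side", "reviewer",
                    "clear", "bifm")


@dataclass
class AgreementResult:
    kappa: float
    n: int
    perm_mean_kappa: dict = field(default_factory=dict)  # per scheme
    p_value: dict = field(default_factory=dict)


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), marginal-product chance."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    cats, a_idx = np.unique(a, return_inverse=True)
    cats_b, b_idx = np.unique(b, return_inverse=True)
    all_cats = np.unique(np.concatenate([cats, cats_b]))
    a_idx = np.searchsorted(all_cats, a)
    b_idx = np.searchsorted(all_cats, b)
    p_o = np.mean(a_idx == b_idx)
    pa = np.bincount(a_idx, minlength=all_cats.size) / a.size
    pb = np.bincount(b_idx, minlength=all_cats.size) / a.size
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1 (both raters constant); kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def permutation_null(
    labels_a,
    labels_b,
    scheme: str = "overall",
    groups=None,
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 500,
) -> tuple[float, float]:
    """Permutation null for kappa; returns (mean null kappa, p-value).

    ``overall`` shuffles reviewer B's labels freely; ``within_seizure``
    shuffles them only inside each seizure's group, preserving per-seizure
    label counts.  Both schemes leave B's marginal distribution unchanged,
    so only the observed agreement varies across permutations.  The
    p-value uses the add-one estimator (1 + #{k_perm >= k_emp}) /
    (n_perm + 1), never exactly zero.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    if scheme not in ("overall", "within_seizure"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "within_seizure":
        if groups is None:
            raise ValueError("within_seizure permutation requires group ids")
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        a_s, b_s, g_s = a[order], b[order], groups[order]
    else:
        a_s, b_s, g_s = a, b, None

    emp = cohen_kappa(a, b)
    # marginals are permutation-invariant => p_e fixed; only p_o varies
    all_cats = np.unique(np.concatenate([np.unique(a), np.unique(b)]))
    ai = np.searchsorted(all_cats, a_s)
    bi = np.searchsorted(all_cats, b_s)
    pa = np.bincount(ai, minlength=all_cats.size) / n
    pb = np.bincount(bi, minlength=all_cats.size) / n
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        raise ValueError("degenerate labels: expected agreement is 1")

    if g_s is not None:
        _, group_codes = np.unique(g_s, return_inverse=True)

    rng = np.random.default_rng(seed)
    kappas = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        if g_s is None:
            perm = np.argsort(keys, axis=1)
        else:
            # sort within contiguous group blocks: group code dominates the
            # key, the random fraction shuffles inside each block
            perm = np.argsort(group_codes[None, :] + 0.999 * keys, axis=1)
        p_o = (bi[perm] == ai[None, :]).mean(axis=1)
        kappas[done : done + m] = (p_o - p_e) / (1.0 - p_e)
        done += m
    p_value = (1.0 + np.sum(kappas >= emp)) / (n_perm + 1.0)
    return float(kappas.mean()), float(p_value)


def _pivot_reviewers(labels: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, seizure, ic, side) with both reviewers' labels."""
    df = labels.copy()
    missing = set(REVIEWER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reviewer label table lacks columns {sorted(missing)}")
    reviewers = sorted(df["reviewer"].unique())
    if len(reviewers) != 2:
        raise ValueError(f"exactly two reviewers required, found {reviewers}")
    key = ["patient_id", "seizure_id", "ic_index", "side"]
    a = df[df.reviewer == reviewers[0]].set_index(key)
    b = df[df.reviewer == reviewers[1]].set_index(key)
    if not a.index.equals(b.index):
        sym = a.index.symmetric_difference(b.index)
        raise ValueError(
            f"reviewers labeled different IC sets; {len(sym)} mismatched keys, "
            f"first few: {list(sym[:3])}"
        )
    out = pd.DataFrame(
        {
            "clear_a": a["clear"].astype(bool),
            "clear_b": b["clear"].astype(bool),
            "bifm_a": a["bifm"],
            "bifm_b": b["bifm"],
        }
    ).reset_index()
    return out


def reconcile_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Final per-IC labels: a class survives only when both reviewers
    marked the IC clear with the same class; anything else is excluded."""
    wide = _pivot_reviewers(labels)
    agreed = (
        wide.clear_a & wide.clear_b & wide.bifm_a.notna()
        & (wide.bifm_a == wide.bifm_b)
    )
    wide["final_bifm"] = wide.bifm_a.where(agreed, None)
    wide["agreed"] = agreed
    return wide


def agreement_report(
    labels: pd.DataFrame, n_perm: int = 10_000, seed: int = 0
) -> dict[str, AgreementResult]:
    """Kappa + permutation nulls per side, on the clear/not and class tasks.

    Mirrors the standard reporting layout: binary clear-transition
    agreement over all ICs, class agreement over all ICs (not-clear coded
    as its own category), and class agreement restricted to ICs both
    reviewers labeled with some class.
    """
    wide = _pivot_reviewers(labels)
    results: dict[str, AgreementResult] = {}
    rng = np.random.default_rng(seed)
    for side in ("onset", "offset"):
        sub = wide[wide.side == side]
        groups = sub.seizure_id.to_numpy()
        blocks = {
            f"clear_transition_{side}": (
                sub.clear_a.to_numpy(), sub.clear_b.to_numpy(), None
            ),
            f"all_bifm_{side}": (
                sub.bifm_a.fillna("none").to_numpy(),
                sub.bifm_b.fillna("none").to_numpy(),
                None,
            ),
        }
        shared = sub[sub.bifm_a.notna() & sub.bifm_b.notna()]
        if len(shared) >= 2:
            blocks[f"shared_bifm_{side}"] = (
                shared.bifm_a.to_numpy(), shared.bifm_b.to_numpy(),
                shared.seizure_id.to_numpy(),
            )
        for name, (la, lb, g) in blocks.items():
            kappa = cohen_kappa(la, lb)
            res = AgreementResult(kappa=kappa, n=la.size)
            g_eff = g if g is not None else groups[: la.size] if la.size == len(sub) else None
            for scheme in ("overall", "within_seizure"):
                grp = g if g is not None else groups
                if scheme == "within_seizure" and la.size != grp.size:
                    continue
                mean_k, p = permutation_null(
                    la, lb, scheme=scheme,
                    groups=grp if scheme == "within_seizure" else None,
                    n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
                )
                res.perm_mean_kappa[scheme] = mean_k
                res.p_value[scheme] = p
            results[name] = res
    return results


def seizure_level_bifm(
    final_labels: pd.DataFrame, objective_measures: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve one class per seizure-side from the agreed ICs.

    When agreed ICs disagree, the IC with the earliest change-point anchor
    wins; anchors closer than 0.5 s are broken by the higher brain score.
    ``objective_measures`` supplies per-IC ``anchor_s`` and ``brain_score``
    (rows keyed by seizure_id, ic_index, side); absent measures default to
    annotation order.  Returns (per-seizure table, summary counts).
    """
    agreed = final_labels[final_labels.agreed].copy()
    if objective_measures is not None:
        agreed = agreed.merge(
            objective_measures, on=["seizure_id", "ic_index", "side"], how="left"
        )
    if "anchor_s" not in agreed.columns:
        agreed["anchor_s"] = np.nan
    if "brain_score" not in agreed.columns:
        agreed["brain_score"] = np.nan
    rows = []
    for (sid, side), grp in agreed.groupby(["seizure_id", "side"], sort=True):
        cats = grp.final_bifm.unique()
        if len(cats) == 1:
            chosen = cats[0]
        else:
            g = grp.copy()
            g["anchor_s"] = g["anchor_s"].fillna(np.inf)
            g = g.sort_values(["anchor_s", "ic_index"])
            first = g.iloc[0]
            near = g[g.anchor_s - first.anchor_s < 0.5]
            if len(near) > 1 and near.brain_score.notna().any():
                first = near.sort_values("brain_score", ascending=False).iloc[0]
            chosen = first.final_bifm
        rows.append(
            {
                "patient_id": grp.patient_id.iloc[0],
                "seizure_id": sid,
                "side": side,
                "bifm": chosen,
                "n_agreed_ics": len(grp),
                "n_unique_bifms": len(cats),
            }
        )
    per_seizure = pd.DataFrame(
        rows, columns=["patient_id", "seizure_id", "side", "bifm",
                       "n_agreed_ics", "n_unique_bifms"]
    )
    summaries = []
    for side in ("onset", "offset"):
        sub = per_seizure[per_seizure.side == side]
        summaries.append(
            {
                "side": side,
                "seizures_with_clear_bifm": len(sub),
                "agreed_ics": int(sub.n_agreed_ics.sum()),
                "agreed_ics_per_seizure": (
                    float(sub.n_agreed_ics.mean()) if len(sub) else np.nan
                ),
                "seizures_with_multiple_bifms": int((sub.n_unique_bifms > 1).sum()),
            }
        )
    return per_seizure, pd.DataFrame(summaries)


def import_reviewer_workbook(path, sheet=0, column_map: dict | None = None) -> pd.DataFrame:
    """Adapter for externally published reviewer-label workbooks.

    Reads an XLSX/CSV table and renames columns to the package schema via
    ``column_map`` (external name -> package name).  The mapped table must
    provide all of :data:`REVIEWER_COLUMNS`.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(REVIEWER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"imported table lacks columns {sorted(missing)}")
    df = df[list(REVIEWER_COLUMNS)].copy()
    df["clear"] = df["clear"].astype(bool)
    df.loc[~df.clear, "bifm"] = None
    return df
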