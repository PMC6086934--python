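"""Greedy marker-gene-set discovery and rule-based neurotransmitter calling.

A marker gene set for a cluster is a small set of genes that are all called
expressed in that cluster but not all expressed in any other cluster.  The
greedy search starts from the most enriched gene, adds the most specific
gene by trinarization, and then extends one gene at a time maximizing the
selectivity of the joint set (ties broken by enrichment), up to six genes.

Reported per prefix length:

- selectivity: 1 / (number of clusters in which all chosen genes are called
  expressed) — monotone non-decreasing as genes are added;
- specificity: gap between the joint posterior probability (product over
  genes of P(theta > f)) of the best and the second-best cluster;
- robustness: joint posterior probability that all genes are detected in
  the target cluster — monotone non-increasing.

Neurotransmitter calling trinarizes transporter/synthesis genes at f = 0.05
(f = 0.2 for Nos1) and assigns a transmitter phenotype only when *every*
gene of the rule's set is called expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_stats import TrinarizationParams, trinarize
from .data_model import ClusterProfile

__all__ = [
    "MarkerSet",
    "TransmitterRules",
    "DEFAULT_TRANSMITTER_RULES",
    "discover_markers",
    "call_neurotransmitters",
]


@dataclass
class MarkerSet:
    cluster: int
    genes: list
    selectivity: list
    specificity: list
    robustness: list

    def __post_init__(self):
        if len(self.genes) > 6:
            raise ValueError("marker sets carry at most six genes")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "n_genes": np.arange(1, len(self.genes) + 1),
                "gene": self.genes,
                "selectivity": self.selectivity,
                "specificity": self.specificity,
                "robustness": self.robustness,
            }
        )


def _expression_calls(profile: ClusterProfile, p: TrinarizationParams):
    """(posterior P, boolean expressed-call) matrices, clusters × genes."""
    if profile.trinaries is None:
        raise ValueError("profile lacks trinarization; run trinarize_profile")
    post = np.asarray(profile.trinaries, dtype=float)
    return post, post > 1.0 - p.pep


def discover_markers(
    profile: ClusterProfile,
    cluster: int,
    trin_params: TrinarizationParams = None,
    max_genes: int = 6,
) -> MarkerSet:
    """Greedy marker set for one cluster (see module docstring).

    Candidate genes are required to be called expressed in the target
    cluster.  The search stops early once selectivity reaches 1.
    """
    trin_params = trin_params or TrinarizationParams()
    if profile.enrichment is None:
        raise ValueError("profile lacks enrichment scores")
    ids = list(profile.cluster_ids)
    if cluster not in ids:
        raise ValueError(f"cluster {cluster} not present in the profile")
    ci = ids.index(cluster)
    post, expressed = _expression_calls(profile, trin_params)
    enr = np.asarray(profile.enrichment, dtype=float)
    candidates = np.flatnonzero(expressed[ci])
    if len(candidates) == 0:
        raise ValueError(f"cluster {cluster} has no genes called expressed")

    others = np.arange(profile.n_clusters) != ci
    chosen: list[int] = []
    sel_hist, spec_hist, rob_hist = [], [], []
    matching = np.ones(profile.n_clusters, dtype=bool)  # all genes so far expressed
    joint_post = np.ones(profile.n_clusters)

    def _stats(gene_set_matching, gene_set_post):
        selectivity = 1.0 / max(int(gene_set_matching.sum()), 1)
        order = np.sort(gene_set_post)[::-1]
        specificity = float(order[0] - order[1]) if len(order) > 1 else float(order[0])
        robustness = float(gene_set_post[ci])
        return selectivity, specificity, robustness

    for step in range(max_genes):
        remaining = np.array([g for g in candidates if g not in chosen])
        if len(remaining) == 0:
            break
        if step == 0:
            pick = remaining[np.argmax(enr[ci, remaining])]
        elif step == 1:
            gap = post[ci, remaining] - np.max(post[others][:, remaining], axis=0)
            pick = remaining[np.lexsort((-enr[ci, remaining], -gap))[0]]
        else:
            n_match = np.array(
                [(matching & expressed[:, g]).sum() for g in remaining]
            )
            best = n_match.min()
            tied = remaining[n_match == best]
            pick = tied[np.argmax(enr[ci, tied])]
        chosen.append(int(pick))
        matching = matching & expressed[:, pick]
        joint_post = joint_post * post[:, pick]
        s, sp_, r = _stats(matching, joint_post)
        sel_hist.append(s)
        spec_hist.append(sp_)
        rob_hist.append(r)
        if s >= 1.0:
            break

    return MarkerSet(
        cluster=cluster,
        genes=[str(profile.gene_symbols[g]) for g in chosen],
        selectivity=sel_hist,
        specificity=spec_hist,
        robustness=rob_hist,
    )


def discover_all_markers(
    profile: ClusterProfile, trin_params: TrinarizationParams = None, max_genes: int = 6
) -> pd.DataFrame:
    frames = []
    for c in profile.cluster_ids:
        try:
            frames.append(
                discover_markers(profile, int(c), trin_params, max_genes).as_frame()
            )
        except ValueError as exc:
            warnings.warn(f"cluster {c}: {exc}")
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# neurotransmitter calling
# ---------------------------------------------------------------------------

#: gene sets defining transmitter phenotypes; vesicular glutamate
#: transporters are evaluated separately, all other sets jointly
DEFAULT_TRANSMITTER_RULES = {
    "VGLUT1": (("Slc17a7",), 0.05),
    "VGLUT2": (("Slc17a6",), 0.05),
    "VGLUT3": (("Slc17a8",), 0.05),
    "GABAergic": (("Gad1", "Gad2", "Slc32a1"), 0.05),
    "Glycinergic": (("Slc6a5",), 0.05),
    "Cholinergic": (("Chat", "Slc18a3"), 0.05),
    "Dopaminergic": (("Th", "Slc6a3", "Slc18a2"), 0.05),
    "Noradrenergic": (("Th", "Dbh", "Slc18a2"), 0.05),
    "Serotonergic": (("Tph2", "Slc6a4", "Slc18a2"), 0.05),
    "Nitrergic": (("Nos1",), 0.2),
}


@dataclass
class TransmitterRules:
    """Transmitter name -> (required gene set, detection fraction f)."""

    rules: dict = field(default_factory=lambda: dict(DEFAULT_TRANSMITTER_RULES))

    @classmethod
    def from_yaml(cls, path: str) -> "TransmitterRules":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {}
        for name, entry in raw.items():
            genes = tuple(entry["genes"])
            rules[name] = (genes, float(entry.get("f", 0.05)))
        return cls(rules=rules)


def call_neurotransmitters(
    profile: ClusterProfile,
    rules: TransmitterRules = None,
    trin_params: TrinarizationParams = None,
) -> pd.DataFrame:
    """Per-cluster transmitter label sets.

    A transmitter is assigned to a cluster iff every gene of its rule is
    called expressed at the rule's detection fraction f with the configured
    PEP.  Rules whose genes are absent from the profile are skipped with a
    warning.  Deterministic and idempotent.
    """
    rules = rules or TransmitterRules()
    trin_params = trin_params or TrinarizationParams()
    sym_to_idx = {s: i for i, s in enumerate(profile.gene_symbols)}
    if profile.nonzero_counts is not None:
        k_all = np.asarray(profile.nonzero_counts, dtype=float)
    else:
        k_all = np.rint(profile.nonzero_frac * profile.cell_counts[:, None])
    n = profile.cell_counts.astype(float)

    assigned: dict[int, list[str]] = {int(c): [] for c in profile.cluster_ids}
    for name, (genes, f) in rules.rules.items():
        missing = [g for g in genes if g not in sym_to_idx]
        if missing:
            warnings.warn(f"rule {name!r}: genes {missing} absent; rule skipped")
            continue
        params = TrinarizationParams(
            a=trin_params.a, b=trin_params.b, f=f, pep=trin_params.pep
        )
        ok = np.ones(profile.n_clusters, dtype=bool)
        for g in genes:
            prob, _ = trinarize(k_all[:, sym_to_idx[g]], n, params)
            ok &= np.asarray(prob) > 1.0 - params.pep
        for ci in np.flatnonzero(ok):
            assigned[int(profile.cluster_ids[ci])].append(name)
    return pd.DataFrame(
        {
            "cluster": list(assigned),
            "transmitters": [";".join(v) for v in assigned.values()],
        }
    )
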