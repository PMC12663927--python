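"""Synthetic datasets with the statistical structure the analyses assume.

The generator produces, from one seed, a complete desk-scale stand-in
for a rubisco kinetic survey:

* a random coalescent tree over ``n_leaves`` taxa;
* protein sequences evolved site-independently down the tree under a
  uniform 20-state jump model (sequences are born aligned; no indels);
* a latent ln-rate evolving as Brownian motion along the same tree
  (optionally Ornstein-Uhlenbeck), so similar sequences carry similar
  rates — the phylogenetic signal that identity-based prediction
  exploits — plus additive effects at designated causal positions;
* noisy coupled-assay observations of the characterized subset:
  multiplicative assay bias (the coupled route reads ``rate / beta``),
  per-batch scale factors, log-normal measurement noise, and assay
  temperatures away from 30 degC governed by a true Q10;
* a control variant measured in every batch, and a paired
  coupled/direct table for calibrating the assay correction.

Within a clade (form) the true rates are log-normal by construction:
leaf ln-rates are Gaussian under the Brownian model.

Every stochastic choice flows from the single ``seed`` in
:class:`SimConfig`; a fixed config reproduces the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import kinetics
from .seqspace import AMINO_ACIDS, AlignedSeqSet, write_alignment, write_metadata

_N_AA = len(AMINO_ACIDS)


@dataclass
class CausalSite:
    """A position whose residue shifts the ln-rate additively.

    With ``residue=None`` (the default) the site is *planted as a
    convergent trait*: a random ``carrier_fraction`` of leaves, drawn
    independently of the tree, receives a trigger residue at the
    position and the delta on their ln-rate.  Because carriers are
    i.i.d. across leaves, the causal indicator is not confounded with
    clade-defining substitutions at other positions — the recoverable
    planted-signal scenario.  Passing an explicit ``residue`` instead
    leaves the simulated column untouched and triggers on whoever
    happens to carry that residue, phylogenetic linkage included.
    """

    position: int
    delta: float = 1.0
    residue: str | None = None
    carrier_fraction: float = 0.5


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study's statistical shape.

    The substitution rate and trait variance are matched jointly so that
    variant pairs at >= 50% identity differ by less than about twofold in
    rate (the observed smooth-rate-landscape regime) while pairs above
    90% identity are nearly equal; the root ln-rate puts the central
    simulated rate at 7 s^-1 and the coupled assay underestimates by the
    study-scale factor 2.1.
    """

    n_leaves: int = 150
    length: int = 300
    mu: float = 0.2            # substitutions per site per unit branch length
    sigma2: float = 0.25       # BM variance of ln-rate per unit branch length
    y0: float = float(np.log(7.0))  # root ln-rate (ln s^-1)
    ou_theta: float = 0.0      # OU mean reversion; 0 = pure Brownian motion
    causal_sites: list[CausalSite] = field(default_factory=list)
    form_names: tuple[str, ...] = ("I", "II", "II/III", "III")
    form_weights: tuple[float, ...] = (0.4, 0.25, 0.15, 0.2)
    root_depth: float = 2.5  # forms join the root at this depth (coalescent units)
    frac_characterized: float = 0.25
    # how the characterized panel is chosen: "screen" mimics a sequential
    # diversity screen — greedy cluster centroids collected at a ladder
    # of identity thresholds (coarse first), topped up with random
    # leaves as denser literature-like extras; "random" is a uniform
    # subsample.  The screen gives the panel a broad nearest-neighbour
    # identity spectrum, which is what makes identity-thresholded
    # cross-validation informative.
    characterized_mode: str = "screen"
    screen_thresholds: tuple[float, ...] = (0.55, 0.7, 0.8, 0.85, 0.9, 0.95)
    beta: float = 2.1          # coupled assay observes rate / beta
    sigma_obs: float = 0.2     # ln-space measurement noise
    batch_sigma: float = 0.1   # ln-space spread of per-batch scale factors
    n_batches: int = 8
    control_true_rate: float = 5.0  # control variant's true rate at 30 degC
    control_id: str = "control"
    temp_mean: float = 25.0    # assay temperature distribution, degC
    temp_sd: float = 3.0
    true_q10: float = 2.2
    n_pairs: int = 11          # variants measured by both assay routes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if min(self.mu, self.sigma2, self.beta, self.control_true_rate) < 0:
            raise ValueError("rates and variances must be non-negative")
        for site in self.causal_sites:
            if not 0 <= site.position < self.length:
                raise ValueError("causal position outside the sequence")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        data["causal_sites"] = [CausalSite(**c) for c in data.get("causal_sites", [])]
        for tup in ("form_names", "form_weights", "screen_thresholds"):
            if tup in data:
                data[tup] = tuple(data[tup])
        return cls(**data)


@dataclass
class SyntheticDataset:
    """A generated survey: tree, alignment, truth, and observations."""

    config: SimConfig
    tree: dendropy.Tree
    newick: str
    aln: AlignedSeqSet
    true_ln_rates: dict[str, float]
    records: pd.DataFrame          # observed coupled-assay rate table
    pairs: pd.DataFrame            # variant_id, k_coupled, k_direct
    truth: dict

    @property
    def characterized_ids(self) -> list[str]:
        return [s for s, c in zip(self.aln.ids, self.aln.characterized) if c]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _kingman_newick(
    labels: Sequence[str], rng: np.random.Generator, pop_size: float = 1.0
) -> tuple[str, float]:
    """Kingman coalescent over the labels; returns (newick clause, height).

    Pairs merge at rate C(k,2)/pop_size; branch lengths are in
    coalescent units.  A single label yields a zero-height leaf clause.
    """
    nodes = [(lab, 0.0) for lab in labels]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(pop_size / (k * (k - 1) / 2))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = (f"({na}:{t - ha:.10f},{nb}:{t - hb:.10f})", t)
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [merged]
    return nodes[0]


def simulate_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Random Kingman coalescent tree with unit population size.

    Branch lengths are in coalescent units (expected height ~2 for large
    trees); leaves are labelled ``v000, v001, ...``.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    labels = [f"v{i:03d}" for i in range(n_leaves)]
    clause, _ = _kingman_newick(labels, np.random.default_rng(seed))
    return dendropy.Tree.get(data=clause + ";", schema="newick")


def simulate_form_forest(
    n_leaves: int,
    form_names: Sequence[str],
    form_weights: Sequence[float],
    root_depth: float,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """One coalescent subtree per form, joined at a deep root.

    Emulates the deep divergence between the enzyme forms: within-form
    structure is a Kingman coalescent, and the forms hang off a common
    root at ``root_depth``, so between-form sequence identity is much
    lower than within-form identity.  Returns the tree and the
    leaf-label -> form map.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(form_weights, float)
    w = w / w.sum()
    counts = np.floor(w * n_leaves).astype(int)
    while counts.sum() < n_leaves:  # distribute the remainder by weight
        counts[int(np.argmax(w * n_leaves - counts))] += 1
    clauses = []
    form_of: dict[str, str] = {}
    start = 0
    for form, nf in zip(form_names, counts):
        if nf == 0:
            continue
        labels = [f"v{start + i:03d}" for i in range(nf)]
        start += nf
        for lab in labels:
            form_of[lab] = form
        clause, height = _kingman_newick(labels, rng)
        stem = max(root_depth - height, 0.05)
        clauses.append(f"{clause}:{stem:.10f}")
    newick = "(" + ",".join(clauses) + ");"
    return dendropy.Tree.get(data=newick, schema="newick"), form_of


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Sequence and trait evolution
# ---------------------------------------------------------------------------

def _evolve_sequences(
    tree: dendropy.Tree, length: int, mu: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Uniform 20-state jump model, site-independent; returns leaf arrays
    of residue indices (0..19)."""
    seqs: dict[int, np.ndarray] = {}
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, _N_AA, size=length)
        else:
            t = node.edge.length or 0.0
            # P(site differs from parent) under equal-exchange jumps
            p_change = (_N_AA - 1) / _N_AA * (1.0 - np.exp(-_N_AA / (_N_AA - 1) * mu * t))
            seq = seqs[id(node.parent_node)].copy()
            flip = rng.random(length) < p_change
            k = int(flip.sum())
            if k:
                offset = rng.integers(1, _N_AA, size=k)
                seq[flip] = (seq[flip] + offset) % _N_AA
        seqs[id(node)] = seq
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = seq
    return leaf_seqs


def _evolve_trait(
    tree: dendropy.Tree,
    y0: float,
    sigma2: float,
    theta: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Brownian motion (theta=0) or OU ln-rate along the tree."""
    vals: dict[int, float] = {}
    leaves: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            y = y0
        else:
            t = node.edge.length or 0.0
            parent = vals[id(node.parent_node)]
            if theta > 0:
                decay = np.exp(-theta * t)
                mean = y0 + (parent - y0) * decay
                var = sigma2 / (2 * theta) * (1.0 - decay**2)
            else:
                mean = parent
                var = sigma2 * t
            y = mean + rng.normal(0.0, np.sqrt(var)) if var > 0 else mean
        vals[id(node)] = float(y)
        if node.is_leaf():
            leaves[node.taxon.label] = float(y)
    return leaves


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate sequences, true rates and noisy assay observations."""
    # the tree and the downstream draws use independent seeded streams
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    )
    tree, forms = simulate_form_forest(
        cfg.n_leaves, cfg.form_names, cfg.form_weights, cfg.root_depth, seed=cfg.seed
    )
    leaf_seqs = _evolve_sequences(tree, cfg.length, cfg.mu, rng)
    traits = _evolve_trait(tree, cfg.y0, cfg.sigma2, cfg.ou_theta, rng)

    ids = sorted(leaf_seqs)
    seq_arr = np.stack([leaf_seqs[sid] for sid in ids])

    # resolve causal sites; planted (convergent) sites rewrite their column
    resolved_sites = []
    for site in cfg.causal_sites:
        col = seq_arr[:, site.position]
        if site.residue is None:
            # trigger = rarest residue at the column; carriers i.i.d.
            counts = np.bincount(col, minlength=_N_AA)
            trigger = int(np.argmin(counts))
            carriers = rng.random(len(ids)) < site.carrier_fraction
            clash = (~carriers) & (col == trigger)
            if clash.any():  # non-carriers must not show the trigger
                col[clash] = (col[clash] + rng.integers(1, _N_AA, int(clash.sum()))) % _N_AA
            col[carriers] = trigger
            seq_arr[:, site.position] = col
            residue = AMINO_ACIDS[trigger]
        else:
            residue = site.residue
        resolved_sites.append(
            {"position": site.position, "residue": residue, "delta": site.delta}
        )
    rows = ["".join(AMINO_ACIDS[k] for k in seq) for seq in seq_arr]
    true_ln = {}
    for sid, row in zip(ids, rows):
        y = traits[sid]
        for site in resolved_sites:
            if row[site["position"]] == site["residue"]:
                y += site["delta"]
        true_ln[sid] = float(y)

    n_char = int(round(cfg.frac_characterized * cfg.n_leaves))
    aln_plain = AlignedSeqSet(ids=list(ids), rows=list(rows))
    if cfg.characterized_mode == "screen":
        from .seqspace import greedy_cluster

        panel: list[str] = []
        for thr in cfg.screen_thresholds:
            if len(panel) >= n_char:
                break
            for cid in greedy_cluster(aln_plain, thr).centroid_ids:
                if cid not in panel:
                    panel.append(cid)
                    if len(panel) >= n_char:
                        break
        remaining = [s for s in ids if s not in set(panel)]
        if len(panel) < n_char:
            extra = rng.choice(remaining, size=n_char - len(panel), replace=False)
            panel = panel + list(extra)
        char_ids = set(panel[:n_char])
    elif cfg.characterized_mode == "random":
        char_ids = set(rng.choice(ids, size=n_char, replace=False).tolist())
    else:
        raise ValueError(f"unknown characterized_mode {cfg.characterized_mode!r}")

    aln = AlignedSeqSet(
        ids=ids,
        rows=rows,
        form=[forms[s] for s in ids],
        characterized=[s in char_ids for s in ids],
        complete=[True] * len(ids),
    )

    # observation model: coupled assay at off-target temperatures with
    # batch scaling and log-normal noise; control in every batch
    batch_scales = np.exp(rng.normal(0.0, cfg.batch_sigma, size=cfg.n_batches))
    char_sorted = [s for s in ids if s in char_ids]
    rec_rows = []

    def _observe(sid: str, true_30: float, batch: int) -> tuple:
        temp = float(np.clip(rng.normal(cfg.temp_mean, cfg.temp_sd), 10.0, 40.0))
        kcat = (
            true_30
            * cfg.true_q10 ** ((temp - 30.0) / 10.0)
            / cfg.beta
            * batch_scales[batch]
            * np.exp(rng.normal(0.0, cfg.sigma_obs))
        )
        return (sid, float(kcat), temp, "coupled", f"b{batch:02d}", "pipeline")

    for k, sid in enumerate(char_sorted):
        batch = k % cfg.n_batches
        rec_rows.append(_observe(sid, float(np.exp(true_ln[sid])), batch))
    for batch in range(cfg.n_batches):
        rec_rows.append(_observe(cfg.control_id, cfg.control_true_rate, batch))
    records = kinetics.make_rate_table(
        pd.DataFrame(rec_rows, columns=kinetics.RATE_COLUMNS)
    )

    # paired coupled/direct table for the assay-correction fit
    n_pairs = min(cfg.n_pairs, len(char_sorted))
    pair_ids = rng.choice(char_sorted, size=n_pairs, replace=False).tolist()
    pair_rows = []
    for sid in pair_ids:
        true_30 = float(np.exp(true_ln[sid]))
        k_coupled = true_30 / cfg.beta * np.exp(rng.normal(0.0, cfg.sigma_obs))
        k_direct = true_30 * np.exp(rng.normal(0.0, cfg.sigma_obs))
        pair_rows.append((sid, float(k_coupled), float(k_direct)))
    pairs = pd.DataFrame(pair_rows, columns=["variant_id", "k_coupled", "k_direct"])

    truth = {
        "beta": cfg.beta,
        "true_q10": cfg.true_q10,
        "y0": cfg.y0,
        "sigma2": cfg.sigma2,
        "mu": cfg.mu,
        "causal_sites": resolved_sites,
        "batch_scales": batch_scales.tolist(),
        "control_reference_coupled": cfg.control_true_rate / cfg.beta,
        "control_true_rate": cfg.control_true_rate,
        "n_characterized": n_char,
    }
    return SyntheticDataset(
        config=cfg,
        tree=tree,
        newick=tree_to_newick(tree),
        aln=aln,
        true_ln_rates=true_ln,
        records=records,
        pairs=pairs,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + metadata TSV + rates CSV + pairs CSV + newick + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "rates": outdir / "rates.csv",
        "pairs": outdir / "pairs.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    write_alignment(ds.aln, paths["alignment"])
    write_metadata(ds.aln, paths["metadata"])
    kinetics.write_rates(ds.records, paths["rates"])
    ds.pairs.to_csv(paths["pairs"], index=False)
    paths["tree"].write_text(ds.newick + "\n")
    truth = dict(ds.truth)
    truth["true_ln_rates"] = ds.true_ln_rates
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def simulate_assay_pairs(
    n_pairs: int = 11,
    beta: float = 2.1,
    sigma_obs: float = 0.2,
    seed: int = 0,
    ln_rate_range: tuple[float, float] = (0.0, 3.0),
) -> pd.DataFrame:
    """Paired coupled/direct observations of shared variants.

    True 30 degC ln-rates are drawn uniformly over ``ln_rate_range``;
    the coupled route reads ``rate / beta`` and both routes carry
    independent log-normal noise of scale ``sigma_obs``.
    """
    rng = np.random.default_rng(seed)
    true = np.exp(rng.uniform(*ln_rate_range, size=n_pairs))
    k_coupled = true / beta * np.exp(rng.normal(0.0, sigma_obs, n_pairs))
    k_direct = true * np.exp(rng.normal(0.0, sigma_obs, n_pairs))
    return pd.DataFrame(
        {
            "variant_id": [f"p{i:02d}" for i in range(n_pairs)],
            "k_coupled": k_coupled,
            "k_direct": k_direct,
        }
    )


# ---------------------------------------------------------------------------
# Parameter-recovery experiment
# ---------------------------------------------------------------------------

def harmonize_observations(
    ds: SyntheticDataset,
    q10: float = kinetics.DEFAULT_Q10,
    correction: kinetics.CorrectionFit | None = None,
) -> tuple[pd.DataFrame, kinetics.CorrectionFit]:
    """Run the pipeline harmonization chain on a synthetic survey.

    Q10-corrects every record to 30 degC, normalizes each batch to the
    control variant's coupled-scale reference, fits the assay correction
    on the paired table (unless a fit is supplied) and applies it.
    Control records are dropped from the returned table.
    """
    corrected = kinetics.q10_correct(ds.records, q10=q10)
    normalized, _report = kinetics.normalize_to_control(
        corrected,
        control_id=ds.config.control_id,
        control_reference=ds.truth["control_reference_coupled"],
    )
    fit = correction or kinetics.fit_assay_correction(
        ds.pairs[["k_coupled", "k_direct"]].to_numpy()
    )
    final = kinetics.apply_correction(normalized, fit)
    final = final[final["variant_id"] != ds.config.control_id].reset_index(drop=True)
    return final, fit


def recovery_experiment(
    cfg: SimConfig,
    cv_thresholds: Sequence[float] = (0.5, 0.8, 0.9),
    model_kind: str = "svr_rbf",
    association_iterations: int = 100,
) -> dict:
    """Full-chain recovery of the injected parameters from one dataset.

    Simulates a survey, harmonizes the observations, and reports the
    fitted assay factor against the injected bias, the identity-
    thresholded LOO errors, and (when causal sites were planted) the
    association rank of each planted position.
    """
    from .association import AssociationConfig, fit_position_association
    from .predict import ModelSpec, loo_crossval, one_hot_encode

    ds = simulate_dataset(cfg)
    final, fit = harmonize_observations(ds)

    harmonized = kinetics.collapse_replicates(final)
    char = ds.aln.subset_ids(list(harmonized.index))
    ln_obs = {v: float(np.log(harmonized[v])) for v in harmonized.index}
    spec = ModelSpec(kind=model_kind)
    cv = loo_crossval(char, ln_obs, spec, thresholds=list(cv_thresholds))

    report: dict = {
        "beta_true": cfg.beta,
        "beta_hat": fit.factor,
        "beta_ci": (fit.ci_low, fit.ci_high),
        "beta_covered": fit.ci_low <= cfg.beta <= fit.ci_high,
        "cv": cv,
        "median_true": float(np.median(np.exp(list(ds.true_ln_rates.values())))),
        "median_harmonized": float(np.median(harmonized.to_numpy())),
        "dataset": ds,
    }
    if cfg.causal_sites:
        enc = one_hot_encode(char)
        y = np.array([ln_obs[v] for v in char.ids])
        assoc = fit_position_association(
            enc,
            y,
            AssociationConfig(n_iterations=association_iterations, seed=cfg.seed),
        )
        report["causal_ranks"] = {
            site["position"]: assoc.rank_of_column(site["position"])
            for site in ds.truth["causal_sites"]
        }
        report["association"] = assoc
    return report
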