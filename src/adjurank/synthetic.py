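"""Seeded generator of ontology-shaped knowledge graphs with planted signal.

The generator emulates the structure of a curated vaccine-adjuvant knowledge
base: four node types, sparse disease-adjuvant positives, class-structured
adjuvants whose functional class correlates with their innate-immune pathway
cues, and node text that carries partial mechanism signal.  Concretely:

* every adjuvant has a latent primary pathway (optionally a secondary one);
  its observed cue row is that multi-hot vector, hidden for a fraction of
  adjuvants ("unknown mechanism"); its functional class is the primary
  pathway's class with a small label-noise probability;
* diseases belong to pathogen families (intracellular bacterium, RNA virus,
  helminth, ...); each family has a characteristic mechanism-demand profile
  over pathways (e.g. intracellular pathogens demand Th1-driving TLR
  agonism) and each disease's latent demand is its family profile plus
  individual variation.  Disease text names the family, not the pathways —
  so zero-shot transfer must go through learned family→mechanism structure,
  while adjuvant text mentions its best-aligned family only part of the
  time (the partial lexical bridge that keeps the text baseline clearly
  above random yet clearly below a model that learns the full
  family→pathway map);
* a (disease, adjuvant) pair is positive with probability
  sigmoid(beta * z + b) where z is the standardized demand·cue alignment and
  the intercept b is calibrated so the expected number of positives per
  disease hits the configured target.  beta = 0 is the null model: positives
  are independent of mechanism by construction;
* each positive pair of a *transductive* disease is connected through a
  vaccine node (vaccine-targets-disease, vaccine-uses-adjuvant,
  vaccine-on-platform).  Inductive diseases keep their node and text but get
  no edges — their positives exist only as held-out labels, which is what
  makes the inductive split a genuine zero-shot evaluation;
* node text is a bag of pathway/class tokens plus random filler, so the
  text-similarity baseline carries real but partial signal.

Default sizes mirror a desk-scale snapshot of the study conditions:
89 diseases split 48 transductive / 41 inductive, 120 adjuvants, 8 pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import DEFAULT_PATHWAYS
from .kg import Edge, HeteroGraph, Node, write_graph

_FILLER_VOCAB = [f"flr{i}" for i in range(40)]

#: Pathogen families: the token strings deliberately share words across
#: related families ("bacterium", "virus"), mimicking partial lexical
#: confusability of real disease descriptions.
_FAMILIES = [
    "intracellular bacterium",
    "extracellular bacterium",
    "rna virus",
    "dna virus",
    "helminth parasite",
    "fungal pathogen",
]


@dataclass(frozen=True)
class SynthConfig:
    n_disease: int = 89
    n_inductive: int = 41
    n_adjuvant: int = 120
    n_platform: int = 6
    n_extra_vaccine: int = 10  # vaccines with no adjuvant edge (platform/disease only)
    n_pathways: int = 8
    n_classes: int = 8
    n_families: int = 6
    family_mix: float = 0.8  # weight of the family profile in a disease's demand
    affinity_mention_p: float = 0.7  # P(adjuvant text names its best-aligned family)
    signal_strength: float = 4.0  # beta: alignment -> positive log-odds
    positives_per_disease: float = 3.0
    secondary_cue_prob: float = 0.3
    hidden_cue_frac: float = 0.1
    class_noise: float = 0.1
    text_noise: int = 4  # filler tokens per node
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_disease, self.n_adjuvant, self.n_platform, self.n_pathways,
               self.n_classes) < 1:
            raise ValueError("all counts must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0 <= self.n_inductive < self.n_disease:
            raise ValueError("n_inductive must be in [0, n_disease)")
        if self.positives_per_disease >= self.n_adjuvant:
            raise ValueError("positives_per_disease must be < n_adjuvant")

    @property
    def pathway_vocab(self) -> list[str]:
        base = list(DEFAULT_PATHWAYS)
        if self.n_pathways <= len(base):
            return base[: self.n_pathways]
        return base + [f"PWY{i}" for i in range(self.n_pathways - len(base))]


@dataclass
class SyntheticData:
    graph: HeteroGraph
    cues: pd.DataFrame       # adjuvant_id, pathway_token (observed cues)
    positives: pd.DataFrame  # disease_id, adjuvant_id
    classes: pd.DataFrame    # adjuvant_id, class_label
    splits: pd.DataFrame     # disease_id, split
    truth: dict = field(default_factory=dict)


def _calibrate_intercept(z: np.ndarray, beta: float, target_rate: float) -> float:
    """Bisect b so that mean(sigmoid(beta z + b)) = target_rate."""
    lo, hi = -30.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(beta * z + mid).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: SynthConfig) -> SyntheticData:
    """Generate one dataset; bitwise-deterministic given the config (incl. seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    vocab = cfg.pathway_vocab
    P = cfg.n_pathways
    class_names = [f"class-{vocab[i % P]}" if i < P else f"class-x{i}"
                   for i in range(cfg.n_classes)]

    # --- adjuvants: latent pathways, observed cues, classes ----------------
    adj_ids = [f"VO:1{i:06d}" for i in range(cfg.n_adjuvant)]
    latent_cues = np.zeros((cfg.n_adjuvant, P))
    primary = rng.integers(0, P, size=cfg.n_adjuvant)
    cue_rows, class_rows = [], []
    observed_cues = np.zeros((cfg.n_adjuvant, P))
    for i, a in enumerate(adj_ids):
        latent_cues[i, primary[i]] = 1.0
        if P > 1 and rng.random() < cfg.secondary_cue_prob:
            extra = int(rng.integers(0, P - 1))
            extra += extra >= primary[i]
            latent_cues[i, extra] = 1.0
        hidden = rng.random() < cfg.hidden_cue_frac
        if not hidden:
            observed_cues[i] = latent_cues[i]
            for j in np.flatnonzero(latent_cues[i]):
                cue_rows.append((a, vocab[j]))
        cls = int(primary[i]) % cfg.n_classes
        if rng.random() < cfg.class_noise:
            cls = int(rng.integers(0, cfg.n_classes))
        class_rows.append((a, class_names[cls]))

    # --- diseases: family-structured latent demand over pathways -----------
    if cfg.n_families > len(_FAMILIES):
        raise ValueError(f"n_families must be <= {len(_FAMILIES)}")
    dis_ids = [f"disease-{i:03d}" for i in range(cfg.n_disease)]
    fam_of = rng.integers(0, cfg.n_families, size=cfg.n_disease)
    fam_profile = np.zeros((cfg.n_families, P))
    for f in range(cfg.n_families):
        dominant = rng.choice(P, size=min(2, P), replace=False)
        logits = np.zeros(P)
        logits[dominant] = 2.5
        fam_profile[f] = np.exp(logits) / np.exp(logits).sum()
    indiv = np.exp(rng.normal(0.0, 1.0, size=(cfg.n_disease, P)))
    indiv /= indiv.sum(axis=1, keepdims=True)
    demand = cfg.family_mix * fam_profile[fam_of] + (1.0 - cfg.family_mix) * indiv
    demand /= demand.sum(axis=1, keepdims=True)

    # --- positives: logistic link on standardized alignment ----------------
    align = demand @ latent_cues.T
    z = (align - align.mean()) / (align.std() + 1e-12)
    beta = cfg.signal_strength
    b = _calibrate_intercept(z.ravel(), beta, cfg.positives_per_disease / cfg.n_adjuvant)
    prob = expit(beta * z + b)
    pos_mask = rng.random(prob.shape) < prob
    for di in range(cfg.n_disease):  # every disease needs >= 1 positive (IDCG > 0)
        if not pos_mask[di].any():
            p = prob[di] / prob[di].sum()
            pos_mask[di, rng.choice(cfg.n_adjuvant, p=p)] = True

    # --- splits -------------------------------------------------------------
    perm = rng.permutation(cfg.n_disease)
    inductive = {dis_ids[i] for i in perm[: cfg.n_inductive]}
    split_rows = [(d, "inductive" if d in inductive else "transductive") for d in dis_ids]

    # --- nodes, text --------------------------------------------------------
    def fillers(n: int) -> str:
        return " ".join(rng.choice(_FILLER_VOCAB, size=n))

    plat_ids = [f"platform-{i}" for i in range(cfg.n_platform)]
    nodes = [Node(p, "Platform", f"vaccine platform {p} {fillers(2)}") for p in plat_ids]
    class_of = dict(class_rows)
    fam_align = fam_profile @ latent_cues.T  # families x adjuvants
    for i, a in enumerate(adj_ids):
        toks = " ".join(vocab[j] for j in np.flatnonzero(observed_cues[i]))
        affinity = ""
        if rng.random() < cfg.affinity_mention_p:
            best_fam = int(np.argmax(fam_align[:, i]))
            affinity = f"effective against {_FAMILIES[best_fam]} infection"
        nodes.append(Node(a, "Adjuvant",
                          f"adjuvant {i} {toks} {class_of[a]} {affinity} "
                          f"{fillers(cfg.text_noise)}"))
    for di, d in enumerate(dis_ids):
        nodes.append(Node(d, "Disease",
                          f"disease {di} caused by {_FAMILIES[fam_of[di]]} "
                          f"{fillers(cfg.text_noise)}"))

    # --- edges: a vaccine per transductive positive pair --------------------
    edges, pos_rows = [], []
    vac_count = 0
    for di, d in enumerate(dis_ids):
        for ai in np.flatnonzero(pos_mask[di]):
            a = adj_ids[ai]
            pos_rows.append((d, a))
            if d in inductive:
                continue  # held-out labels: no edges for unseen diseases
            v = f"vaccine-{vac_count:04d}"
            vac_count += 1
            plat = plat_ids[int(rng.integers(0, cfg.n_platform))]
            nodes.append(Node(v, "Vaccine", f"vaccine {vac_count} {fillers(2)}"))
            edges += [Edge(v, "vaccine-targets-disease", d),
                      Edge(v, "vaccine-uses-adjuvant", a),
                      Edge(v, "vaccine-on-platform", plat)]
    trans_ids = [d for d in dis_ids if d not in inductive]
    for _ in range(cfg.n_extra_vaccine):
        v = f"vaccine-{vac_count:04d}"
        vac_count += 1
        d = trans_ids[int(rng.integers(0, len(trans_ids)))]
        plat = plat_ids[int(rng.integers(0, cfg.n_platform))]
        nodes.append(Node(v, "Vaccine", f"vaccine {vac_count} {fillers(2)}"))
        edges += [Edge(v, "vaccine-targets-disease", d),
                  Edge(v, "vaccine-on-platform", plat)]

    return SyntheticData(
        graph=HeteroGraph(nodes, edges),
        cues=pd.DataFrame(cue_rows, columns=["adjuvant_id", "pathway_token"]),
        positives=pd.DataFrame(pos_rows, columns=["disease_id", "adjuvant_id"]),
        classes=pd.DataFrame(class_rows, columns=["adjuvant_id", "class_label"]),
        splits=pd.DataFrame(split_rows, columns=["disease_id", "split"]),
        truth={
            "family_of": fam_of,
            "family_profile": fam_profile,
            "demand": demand,
            "latent_cues": latent_cues,
            "observed_cues": observed_cues,
            "alignment": align,
            "alignment_std": z,
            "prob": prob,
            "intercept": b,
            "pathway_vocab": vocab,
            "disease_ids": dis_ids,
            "adjuvant_ids": adj_ids,
        },
    )


PRESETS: dict[str, SynthConfig] = {
    "tiny": SynthConfig(n_disease=3, n_inductive=1, n_adjuvant=4, n_platform=1,
                        n_extra_vaccine=0, n_pathways=3, n_classes=3,
                        positives_per_disease=1.5, text_noise=1),
    "default": SynthConfig(),
    "null": SynthConfig(signal_strength=0.0),
}


def make_fixture(name: str, out_dir: str | Path, seed: int | None = None) -> SyntheticData:
    """Write a preset dataset (nodes/edges/cues/positives/classes/splits TSVs)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    data = generate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_graph(data.graph, out / "edges.tsv", out / "nodes.tsv")
    data.cues.to_csv(out / "cues.tsv", sep="\t", index=False)
    data.positives.to_csv(out / "positives.tsv", sep="\t", index=False)
    data.classes.to_csv(out / "classes.tsv", sep="\t", index=False)
    data.splits.to_csv(out / "splits.tsv", sep="\t", index=False)
    return data
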