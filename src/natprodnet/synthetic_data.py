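"""Seeded generators for synthetic screening data.

Every stage of the pipeline can be exercised without external databases:
the generators here produce descriptor tables with the marginal
statistics of a large natural-product library, scale-free bipartite
interaction networks, docking-score tables with planted strong binders,
and sparse target–disease maps with a planted recoverable indication.

All generators are pure functions of their :class:`GeneratorConfig`:
the same config (including its seed) always yields identical output.
Each generator draws from its own independent random stream so that,
e.g., changing the number of diseases does not perturb the descriptor
table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .chemlib import PCA_DESCRIPTOR_COLUMNS, MoleculeRecord

# Marginal (mean, sd) of each descriptor in a large natural-product
# library; counts are overdispersed (variance well above the mean), the
# continuous descriptors are skewed-positive except AlogP.
DEFAULT_DESCRIPTOR_PARAMS: dict[str, tuple[float, float, str]] = {
    "alogp": (2.788, 3.352, "normal"),
    "mw": (472.6, 265.7, "lognormal"),
    "hbd": (3.4, 4.1, "count"),
    "hba": (7.5, 6.7, "count"),
    "n_rotatable": (6.6, 6.8, "count"),
    "n_rings": (3.7, 2.4, "count"),
    "n_aromatic_rings": (0.9, 1.3, "count"),
    "fpsa": (0.248, 0.128, "truncnorm01"),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate a large-library screen: ~2000 compounds against a
    few hundred targets, compound degrees following a truncated power law
    with exponent 1.125, docking scores with a background well below the
    admissibility threshold, and a 10% sub-population of planted strong
    binders scored in the 9–11 band.
    """

    seed: int = 0
    n_compounds: int = 2000
    n_targets: int = 250
    n_diseases: int = 25
    descriptor_params: dict = field(default_factory=lambda: dict(DEFAULT_DESCRIPTOR_PARAMS))
    degree_exponent: float = 1.125
    max_degree: int = 100
    targets_per_compound_docked: int = 5
    background_score_mean: float = 5.0
    background_score_sd: float = 1.5
    planted_binder_fraction: float = 0.10
    planted_pairs_per_binder: int = 2
    planted_score_range: tuple[float, float] = (9.0, 11.0)
    reference_score_mean: float = 7.5
    reference_score_sd: float = 1.0
    max_targets_per_disease: int = 5
    planted_disease_targets: int = 5

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_targets", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.planted_binder_fraction <= 1.0:
            raise ValueError("planted_binder_fraction must be in [0, 1]")
        lo, hi = self.planted_score_range
        if not lo < hi:
            raise ValueError("planted score range must be increasing")
        if self.degree_exponent <= 0:
            raise ValueError("degree_exponent must be positive")
        for name, (mean, sd, kind) in self.descriptor_params.items():
            if sd < 0:
                raise ValueError(f"descriptor {name}: sd must be >= 0")

    def _rng(self, stream: int) -> np.random.Generator:
        # independent stream per generator, all reproducible from the seed
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class MoleculeFixture:
    """A curated molecule with hand-verified descriptor ground truth."""

    id: str
    smiles: str
    truth: dict

    def to_record(self) -> MoleculeRecord:
        from rdkit import Chem

        return MoleculeRecord(id=self.id, mol=Chem.MolFromSmiles(self.smiles), source="fixture")


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------

def _negbinom_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    p = mean / var
    n = mean * mean / (var - mean)
    return n, p


def gen_descriptor_table(config: GeneratorConfig, n: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Synthetic descriptor matrix with configured marginal means/SDs.

    Continuous positive descriptors are log-normal (parameterized to hit
    the configured mean and sd exactly), AlogP is normal, FPSA is a
    normal truncated to [0, 1], and counts are negative binomial matched
    by moments (Poisson when the variance does not exceed the mean).

    Returns the table and a truth record holding, per column, the exact
    mean of the generating distribution (for truncated distributions this
    is the post-truncation mean, not the nominal location parameter).
    """
    n = config.n_compounds if n is None else n
    rng = config._rng(1)
    cols: dict[str, np.ndarray] = {}
    expected_means: dict[str, float] = {}
    for name, (mean, sd, kind) in config.descriptor_params.items():
        if sd == 0:
            cols[name] = np.full(n, mean)
            expected_means[name] = mean
            continue
        if kind == "normal":
            cols[name] = rng.normal(mean, sd, size=n)
            expected_means[name] = mean
        elif kind == "lognormal":
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            cols[name] = rng.lognormal(mu, np.sqrt(sigma2), size=n)
            expected_means[name] = mean
        elif kind == "truncnorm01":
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            dist = sstats.truncnorm(a, b, loc=mean, scale=sd)
            cols[name] = dist.rvs(size=n, random_state=rng)
            expected_means[name] = float(dist.mean())
        elif kind == "count":
            var = sd * sd
            if var > mean:
                nb_n, nb_p = _negbinom_params(mean, sd)
                cols[name] = rng.negative_binomial(nb_n, nb_p, size=n).astype(float)
            else:
                cols[name] = rng.poisson(mean, size=n).astype(float)
            expected_means[name] = mean
        else:
            raise ValueError(f"unknown descriptor kind {kind!r} for {name}")
    order = [c for c in PCA_DESCRIPTOR_COLUMNS if c in cols] + [
        c for c in cols if c not in PCA_DESCRIPTOR_COLUMNS
    ]
    df = pd.DataFrame({c: cols[c] for c in order})
    df.index = [f"SYN{i:06d}" for i in range(n)]
    df.index.name = "id"
    truth = {"expected_means": expected_means, "n": n, "seed": config.seed}
    return df, truth


# ---------------------------------------------------------------------------
# curated molecule fixtures
# ---------------------------------------------------------------------------

def gen_molecule_fixtures() -> list[MoleculeFixture]:
    """Small curated SMILES set with hand-verified descriptor truths.

    Truth values were counted by hand on the published structures
    (hydrogen-bond donors/acceptors under the N+O / NH+OH convention,
    SSSR rings, assigned carbon stereocenters) or computed from standard
    atomic masses (molecular weights).
    """
    return [
        MoleculeFixture(
            "ethanol", "CCO",
            {"mw": 46.07, "hba": 1, "hbd": 1, "n_rotatable": 0, "n_rings": 0,
             "n_aromatic_rings": 0, "n_carbon": 2, "n_chiral_c": 0, "f_chirality": 0.0},
        ),
        MoleculeFixture(
            "benzene", "c1ccccc1",
            {"mw": 78.11, "hba": 0, "hbd": 0, "n_rings": 1, "n_aromatic_rings": 1,
             "n_carbon": 6, "n_chiral_c": 0, "f_chirality": 0.0},
        ),
        MoleculeFixture(
            "aspirin", "CC(=O)Oc1ccccc1C(=O)O",
            {"mw": 180.16, "hba": 4, "hbd": 1, "n_rings": 1, "n_aromatic_rings": 1,
             "n_carbon": 9, "n_chiral_c": 0},
        ),
        MoleculeFixture(
            "caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
            {"mw": 194.19, "hba": 6, "hbd": 0, "n_rings": 2, "n_carbon": 8, "n_chiral_c": 0},
        ),
        MoleculeFixture(
            # beta-D-glucopyranose: 5 of 6 carbons are stereocenters
            "beta-D-glucopyranose", "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@H]1O",
            {"mw": 180.16, "hba": 6, "hbd": 5, "n_rings": 1, "n_aromatic_rings": 0,
             "n_carbon": 6, "n_chiral_c": 5, "f_chirality": 5.0 / 6.0},
        ),
        MoleculeFixture(
            "quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
            {"mw": 302.24, "hba": 7, "hbd": 5, "n_rings": 3, "n_carbon": 15, "n_chiral_c": 0},
        ),
        MoleculeFixture(
            "genistein", "Oc1ccc(cc1)-c1coc2cc(O)cc(O)c2c1=O",
            {"mw": 270.24, "hba": 5, "hbd": 3, "n_rings": 3, "n_carbon": 15, "n_chiral_c": 0},
        ),
        MoleculeFixture(
            "staurosporine",
            "C[C@@]12[C@@H]([C@@H](C[C@@H](O1)N1C3=CC=CC=C3C3=C4CNC(=O)C4=C4C5=CC=CC=C5N2C4=C31)NC)OC",
            {"mw": 466.54, "hba": 7, "hbd": 2, "n_carbon": 28, "n_chiral_c": 4,
             "f_chirality": 4.0 / 28.0},
        ),
        MoleculeFixture(
            "alanine-R", "N[C@@H](C)C(=O)O",
            {"mw": 89.09, "hba": 3, "hbd": 3, "n_carbon": 3, "n_chiral_c": 1, "f_chirality": 1.0 / 3.0},
        ),
        MoleculeFixture(
            "alanine-S", "N[C@H](C)C(=O)O",
            {"mw": 89.09, "hba": 3, "hbd": 3, "n_carbon": 3, "n_chiral_c": 1, "f_chirality": 1.0 / 3.0},
        ),
        MoleculeFixture(
            # salt: acetate is the larger (heavy-atom) fragment
            "sodium-acetate", "CC(=O)[O-].[Na+]",
            {"n_fragments": 2, "largest_fragment_smiles": "CC(=O)[O-]"},
        ),
    ]


def fixture_smiles_text() -> str:
    """The curated set in SMILES-file format (one ``SMILES id`` line each)."""
    return "".join(f"{f.smiles}\t{f.id}\n" for f in gen_molecule_fixtures())


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def _truncated_powerlaw_degrees(rng: np.random.Generator, gamma: float, kmax: int, n: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1)
    p = ks.astype(float) ** (-gamma)
    p /= p.sum()
    return rng.choice(ks, size=n, p=p)


def gen_interaction_network(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Scale-free bipartite interaction edge list.

    Compound degrees are drawn from a power law with the configured
    exponent, truncated at ``min(max_degree, n_targets)``; each compound
    is then wired to that many *distinct* targets, drawn with
    popularity-skewed weights so the target side is heavy-tailed too.
    Drawing distinct targets directly (rather than pairing stubs and
    discarding multi-edges) realizes every compound degree exactly and
    can never produce parallel edges.
    """
    rng = config._rng(2)
    kmax = min(config.max_degree, config.n_targets)
    degrees = _truncated_powerlaw_degrees(rng, config.degree_exponent, kmax, config.n_compounds)

    # target popularity weights: mild power law over a shuffled rank order
    ranks = rng.permutation(config.n_targets) + 1
    weights = ranks.astype(float) ** -0.8
    weights /= weights.sum()

    target_ids = np.array([f"T{j:04d}" for j in range(config.n_targets)])
    rows = []
    for i, k in enumerate(degrees):
        chosen = rng.choice(config.n_targets, size=int(k), replace=False, p=weights)
        affinity = rng.normal(6.5, 1.2, size=int(k)).clip(min=0.1)
        cid = f"C{i:05d}"
        for t, s in zip(chosen, affinity):
            rows.append((cid, target_ids[t], round(float(s), 4), "experimental"))
    edges = pd.DataFrame(rows, columns=["compound_id", "target_id", "score", "source"])
    truth = {
        "configured_exponent": config.degree_exponent,
        "max_degree": int(kmax),
        "compound_degrees": degrees.tolist(),
        "seed": config.seed,
    }
    return edges, truth


# ---------------------------------------------------------------------------
# docking scores
# ---------------------------------------------------------------------------

def gen_docking_scores(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Docking score table, per-target reference scores, and planted truth.

    Every compound is scored against a small random panel of targets with
    background scores from a truncated normal well below the
    admissibility threshold. A configured fraction of compounds are
    planted strong binders: they receive extra pairs scored inside the
    planted range and strictly above the target's reference-ligand score,
    so they are admissible by construction under the default threshold.
    """
    lo, hi = config.planted_score_range
    rng = config._rng(3)
    target_ids = np.array([f"T{j:04d}" for j in range(config.n_targets)])
    compound_ids = np.array([f"C{i:05d}" for i in range(config.n_compounds)])

    # reference-ligand scores, capped below the planted band's ceiling so a
    # planted score above the reference always exists
    refs = rng.normal(config.reference_score_mean, config.reference_score_sd, size=config.n_targets)
    refs = refs.clip(min=0.5, max=hi - 0.5)
    reference = pd.DataFrame({"target_id": target_ids, "ref_score": np.round(refs, 4)})
    ref_map = dict(zip(target_ids, reference["ref_score"]))

    # background panel
    k = min(config.targets_per_compound_docked, config.n_targets)
    rows = []
    for cid in compound_ids:
        chosen = rng.choice(config.n_targets, size=k, replace=False)
        bg = rng.normal(config.background_score_mean, config.background_score_sd, size=k).clip(min=0.01)
        for t, s in zip(chosen, bg):
            rows.append((cid, target_ids[t], round(float(s), 4)))

    # planted binders
    n_planted = int(round(config.planted_binder_fraction * config.n_compounds))
    planted_compounds = rng.choice(compound_ids, size=n_planted, replace=False)
    planted_pairs = []
    for cid in planted_compounds:
        m = min(config.planted_pairs_per_binder, config.n_targets)
        chosen = rng.choice(config.n_targets, size=m, replace=False)
        for t in chosen:
            tid = target_ids[t]
            low = max(lo, ref_map[tid] + 0.05)
            s = round(float(rng.uniform(low, hi)), 4)
            rows.append((cid, tid, s))
            planted_pairs.append((cid, tid, s))

    scores = pd.DataFrame(rows, columns=["compound_id", "target_id", "score"])
    scores["source"] = "docking"
    truth = {
        "planted_compounds": sorted(str(c) for c in planted_compounds),
        "planted_pairs": [(str(c), str(t), s) for c, t, s in planted_pairs],
        "threshold": lo,
        "seed": config.seed,
    }
    return scores, reference, truth


# ---------------------------------------------------------------------------
# disease maps
# ---------------------------------------------------------------------------

def gen_disease_map(
    config: GeneratorConfig, scores: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sparse target–disease map plus a planted recoverable indication.

    Each disease is linked to at least one target. One designated
    compound is given admissible high-band edges to *all* targets of a
    designated disease, so the predictor should rank that (compound,
    disease) pair first; the truth record names the pair.

    Returns (disease links, augmented score table, truth).
    """
    lo, hi = config.planted_score_range
    rng = config._rng(4)
    target_ids = np.array(sorted(reference["target_id"].unique()))
    ref_map = dict(zip(reference["target_id"], reference["ref_score"]))

    links = []
    for j in range(config.n_diseases):
        disease = f"D{j:03d}"
        k = int(rng.integers(1, config.max_targets_per_disease + 1))
        for t in rng.choice(len(target_ids), size=min(k, len(target_ids)), replace=False):
            links.append((target_ids[t], disease))

    # designated disease: fresh target panel, so its coefficient ceiling is known
    planted_disease = f"D{config.n_diseases:03d}"
    m = min(config.planted_disease_targets, len(target_ids))
    disease_targets = target_ids[rng.choice(len(target_ids), size=m, replace=False)]
    for t in disease_targets:
        links.append((t, planted_disease))
    link_df = pd.DataFrame(links, columns=["target_id", "disease"]).drop_duplicates(ignore_index=True)

    planted_compound = f"C{int(rng.integers(config.n_compounds)):05d}"
    extra = []
    for tid in disease_targets:
        low = max(lo, float(ref_map[tid]) + 0.05, hi - 0.4)
        s = round(float(rng.uniform(low, hi)), 4)
        extra.append((planted_compound, tid, s, "docking"))
    augmented = pd.concat(
        [scores, pd.DataFrame(extra, columns=["compound_id", "target_id", "score", "source"])],
        ignore_index=True,
    )
    truth = {
        "planted_compound": planted_compound,
        "planted_disease": planted_disease,
        "planted_disease_targets": [str(t) for t in disease_targets],
        "seed": config.seed,
    }
    return link_df, augmented, truth


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def gen_screening_dataset(config: GeneratorConfig) -> dict:
    """Generate every input the pipeline consumes, as one coherent dataset."""
    descriptors, desc_truth = gen_descriptor_table(config)
    interactions, net_truth = gen_interaction_network(config)
    scores, reference, dock_truth = gen_docking_scores(config)
    links, scores_aug, disease_truth = gen_disease_map(config, scores, reference)
    return {
        "descriptors": descriptors,
        "interactions": interactions,
        "docking_scores": scores_aug,
        "reference_scores": reference,
        "disease_links": links,
        "truth": {
            "descriptors": desc_truth,
            "network": net_truth,
            "docking": dock_truth,
            "indication": disease_truth,
        },
    }


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write the full synthetic dataset in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = gen_screening_dataset(config)
    (out / "molecules.smi").write_text(fixture_smiles_text())
    data["descriptors"].to_csv(out / "descriptors.csv", float_format="%.6g")
    data["interactions"].to_csv(out / "interactions.tsv", sep="\t", index=False, float_format="%.6g")
    data["docking_scores"].to_csv(out / "docking_scores.tsv", sep="\t", index=False, float_format="%.6g")
    data["reference_scores"].to_csv(out / "reference_scores.tsv", sep="\t", index=False, float_format="%.6g")
    data["disease_links"].to_csv(out / "disease_links.tsv", sep="\t", index=False)
    truth = {k: _jsonable(v) for k, v in data["truth"].items()}
    # compound_degrees is bulky; keep the truth file compact but complete
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return data


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
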