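"""Synthetic paired quiescent/activated HSC data with a planted repression network.

The generator emulates the study design the pipeline is built for: a small
number of donors each contributing a quiescent (freshly isolated) and an
activated (culture-passaged) hepatic stellate cell sample, with hepatocyte
and LSEC samples available for the gene matrix only. A planted regulatory
truth assigns each quiescence-enriched miRNA many activation-induced target
genes and each activation-enriched miRNA few quiescence-specific targets,
mirroring the asymmetry the analysis is meant to detect.

Expression is simulated additively on the log2 scale (-dCt for miRNAs, log2
intensity for genes): a baseline, a planted state effect, a per-sample
biological deviation, and measurement noise. For a true pair the miRNA's
biological deviation is propagated into the target gene with a negative
coupling, so miRNA-target pairs are anticorrelated beyond what the shared
state contrast alone would produce. miRNA output is delivered on the raw Ct
scale with a stable reference assay included, so the normalization stage is
exercised end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "RegulatoryTruth",
    "generate_truth",
    "generate_expression",
    "generate_prediction_table",
    "simulate_dataset",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

# sub-ranges for database p-values; disjoint around the 0.05 cut so the
# significance of every emitted pair is unambiguous
_P_SIG = (0.001, 0.04)
_P_NONSIG = (0.06, 0.9)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic dataset.

    Defaults reproduce the design the pipeline targets: 4 donor pairs,
    2 hepatocyte and 3 LSEC samples, ~20 quiescence-enriched miRNAs with a
    mean of 15 activation-induced targets each versus many activation
    miRNAs with ~1.5 targets, strong planted effects (3 log2 units) and
    modest noise on the log2 scale.
    """

    n_donors: int = 4
    n_mirna_q: int = 20
    n_mirna_a: int = 50
    n_genes_q: int = 60
    n_genes_a: int = 150
    n_genes_bg: int = 100
    n_hepatocyte: int = 2
    n_lsec: int = 3
    targets_per_q_mirna: float = 15.0
    targets_per_a_mirna: float = 1.5
    target_count_model: str = "poisson"  # or "fixed"
    effect_log2: float = 3.0
    noise_sd: float = 0.25
    donor_sd: float = 0.5  # per-sample biological deviation on the log2 scale
    coupling: float = 1.0  # repression strength propagated miRNA -> target
    db_sensitivity: float = 0.9
    db_fpr: float = 0.01
    db_background_rate: float = 0.1  # non-pairs listed with non-significant p
    reference_assay: str = "RNU6"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_donors": self.n_donors,
            "n_mirna_q": self.n_mirna_q,
            "n_mirna_a": self.n_mirna_a,
            "n_genes_q": self.n_genes_q,
            "n_genes_a": self.n_genes_a,
            "n_hepatocyte": self.n_hepatocyte,
            "n_lsec": self.n_lsec,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_genes_bg < 0:
            raise ValueError("n_genes_bg must be >= 0")
        for name in ("db_sensitivity", "db_fpr", "db_background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if self.targets_per_q_mirna < 0 or self.targets_per_a_mirna < 0:
            raise ValueError("target-count means must be >= 0")
        if self.target_count_model not in ("poisson", "fixed"):
            raise ValueError(
                f"target_count_model must be 'poisson' or 'fixed', "
                f"got {self.target_count_model!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class RegulatoryTruth:
    """The planted regulatory network behind a simulated dataset."""

    mirna_q: list[str]
    mirna_a: list[str]
    genes_q: list[str]
    genes_a: list[str]
    genes_bg: list[str]
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    effects: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def mirna_ids(self) -> list[str]:
        return self.mirna_q + self.mirna_a

    @property
    def gene_ids(self) -> list[str]:
        return self.genes_q + self.genes_a + self.genes_bg

    def validate(self) -> None:
        mirnas = set(self.mirna_ids)
        genes = set(self.gene_ids)
        q_mir, a_gene = set(self.mirna_q), set(self.genes_a)
        a_mir, q_gene = set(self.mirna_a), set(self.genes_q)
        for m, g in self.true_pairs:
            if m not in mirnas or g not in genes:
                raise ValueError(f"true pair ({m}, {g}) references unknown ids")
            opposite = (m in q_mir and g in a_gene) or (m in a_mir and g in q_gene)
            if not opposite:
                raise ValueError(
                    f"true pair ({m}, {g}) does not link opposite-direction features"
                )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one top-level seed, deterministic child stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_truth(config: SimulationConfig) -> RegulatoryTruth:
    """Plant the regulatory network: partitioned ids plus repressive pairs.

    Quiescence miRNAs draw target counts from the high-mean distribution over
    activation-induced genes; activation miRNAs draw from the low-mean one
    over quiescence-specific genes. Deterministic given the config seed.
    """
    config.validate()
    rng = _rng(config, 1)
    truth = RegulatoryTruth(
        mirna_q=[f"miR-q-{i + 1:03d}" for i in range(config.n_mirna_q)],
        mirna_a=[f"miR-a-{i + 1:03d}" for i in range(config.n_mirna_a)],
        genes_q=[f"GQ{i + 1:04d}" for i in range(config.n_genes_q)],
        genes_a=[f"GA{i + 1:04d}" for i in range(config.n_genes_a)],
        genes_bg=[f"GB{i + 1:04d}" for i in range(config.n_genes_bg)],
    )

    def draw_count(mean: float) -> int:
        if config.target_count_model == "fixed":
            return int(round(mean))
        return int(rng.poisson(mean))

    for mirnas, pool, mean in (
        (truth.mirna_q, truth.genes_a, config.targets_per_q_mirna),
        (truth.mirna_a, truth.genes_q, config.targets_per_a_mirna),
    ):
        for m in mirnas:
            k = draw_count(mean)
            if k > len(pool):
                raise ValueError(
                    f"miRNA {m} requests {k} targets but only {len(pool)} "
                    f"opposite-direction genes are available "
                    f"(shortfall of {k - len(pool)})"
                )
            for g in rng.choice(pool, size=k, replace=False):
                truth.true_pairs.add((m, str(g)))
                truth.effects[(m, str(g))] = config.coupling
    truth.validate()
    return truth


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_donors):
        d = f"D{i + 1}"
        rows.append((f"qHSC_{d}", "HSC", "quiescent", d))
        rows.append((f"aHSC_{d}", "HSC", "activated", d))
    for i in range(config.n_hepatocyte):
        rows.append((f"HEP_{i + 1}", "hepatocyte", "n/a", f"HD{i + 1}"))
    for i in range(config.n_lsec):
        rows.append((f"LSEC_{i + 1}", "LSEC", "n/a", f"LD{i + 1}"))
    return pd.DataFrame(rows, columns=["sample_id", "cell_type", "state", "donor_id"])


def generate_expression(
    truth: RegulatoryTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (Ct matrix, gene log2 matrix, sample sheet) from the truth.

    miRNAs: -dCt = baseline + effect_log2 in the enriched state + biological
    deviation + noise; delivered as Ct against a stable reference assay.
    Genes: log2 = baseline + effect_log2 in the enriched HSC state (quiescence
    genes are elevated only in qHSC samples) minus the coupled deviations of
    the planted regulator miRNAs, plus noise. Hepatocyte/LSEC samples sit at
    baseline for every gene.
    """
    config.validate()
    truth.validate()
    rng = _rng(config, 2)
    sheet = _sample_sheet(config)
    hsc = sheet[sheet["cell_type"] == "HSC"]
    hsc_samples = hsc["sample_id"].tolist()
    is_q = (hsc["state"] == "quiescent").to_numpy()
    n_hsc = len(hsc_samples)

    # --- miRNAs on the -dCt scale ------------------------------------------
    mirnas = truth.mirna_ids
    n_m = len(mirnas)
    base_m = rng.uniform(-8.0, -3.0, size=n_m)
    enriched_in_q = np.array([m in set(truth.mirna_q) for m in mirnas])
    state_ind = np.where(enriched_in_q[:, None], is_q[None, :], ~is_q[None, :])
    bio = rng.normal(0.0, config.donor_sd, size=(n_m, n_hsc))
    eps_m = rng.normal(0.0, config.noise_sd, size=(n_m, n_hsc))
    ndct = base_m[:, None] + config.effect_log2 * state_ind + bio + eps_m
    ndct = pd.DataFrame(ndct, index=mirnas, columns=hsc_samples)

    ref_ct = 20.0 + rng.normal(0.0, 0.1, size=n_hsc)  # state-independent
    ct = pd.DataFrame(
        ref_ct[None, :] - ndct.to_numpy(), index=mirnas, columns=hsc_samples
    )
    ct.loc[config.reference_assay] = ref_ct
    ct.index.name = "assay_id"

    # --- genes on the log2 scale -------------------------------------------
    genes = truth.gene_ids
    all_samples = sheet["sample_id"].tolist()
    n_g = len(genes)
    base_g = rng.uniform(4.0, 10.0, size=n_g)
    expr = np.tile(base_g[:, None], (1, len(all_samples)))
    expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    hsc_cols = [all_samples.index(s) for s in hsc_samples]
    regulators: dict[str, list[str]] = {}
    for m, g in truth.true_pairs:
        regulators.setdefault(g, []).append(m)
    mir_pos = {m: i for i, m in enumerate(mirnas)}
    gene_dir_q = {g: True for g in truth.genes_q}
    gene_dir_q.update({g: False for g in truth.genes_a})

    for gi, g in enumerate(genes):
        if g in gene_dir_q:  # deregulated gene: planted state effect in HSCs
            ind = is_q if gene_dir_q[g] else ~is_q
            expr[gi, hsc_cols] += config.effect_log2 * ind
        regs = regulators.get(g)
        if regs:
            # repression: the regulators' biological deviations, negatively
            # coupled and averaged, replace the gene's own HSC-sample deviation
            coupled = np.mean(
                [truth.effects[(m, g)] * bio[mir_pos[m]] for m in regs], axis=0
            )
            expr[gi, hsc_cols] -= coupled
        else:
            expr[gi, hsc_cols] += rng.normal(0.0, config.donor_sd, size=n_hsc)
    expr = pd.DataFrame(expr, index=genes, columns=all_samples)
    expr.index.name = "gene_id"
    return ct, expr, sheet


def generate_prediction_table(
    truth: RegulatoryTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Emulate a sequence-based target-prediction database.

    Every true pair is listed: with probability ``db_sensitivity`` its
    p_database falls in the significant sub-range (< 0.05), otherwise in the
    non-significant one. A non-pair is listed significantly with probability
    ``db_fpr`` and non-significantly with probability ``db_background_rate``;
    otherwise it is absent.
    """
    config.validate()
    rng = _rng(config, 3)
    mirnas = truth.mirna_ids
    genes = truth.gene_ids
    n_pairs = len(mirnas) * len(genes)
    mir_col = np.repeat(mirnas, len(genes))
    gene_col = np.tile(genes, len(mirnas))
    true_mask = np.zeros(n_pairs, dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mir_pos = {m: i for i, m in enumerate(mirnas)}
    for m, g in truth.true_pairs:
        true_mask[mir_pos[m] * len(genes) + gene_pos[g]] = True

    u = rng.random(n_pairs)
    p_sig = rng.uniform(*_P_SIG, size=n_pairs)
    p_non = rng.uniform(*_P_NONSIG, size=n_pairs)

    listed = np.zeros(n_pairs, dtype=bool)
    p = np.empty(n_pairs)
    # true pairs: always listed, significant with prob db_sensitivity
    listed[true_mask] = True
    sig_true = u < config.db_sensitivity
    p[true_mask & sig_true] = p_sig[true_mask & sig_true]
    p[true_mask & ~sig_true] = p_non[true_mask & ~sig_true]
    # non-pairs: significant with prob db_fpr, else background listing
    non = ~true_mask
    fp = non & (u < config.db_fpr)
    bg = non & (u >= config.db_fpr) & (u < config.db_fpr + config.db_background_rate)
    listed[fp | bg] = True
    p[fp] = p_sig[fp]
    p[bg] = p_non[bg]

    return pd.DataFrame(
        {
            "mirna_id": mir_col[listed],
            "gene_id": gene_col[listed],
            "p_database": p[listed],
        }
    ).reset_index(drop=True)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: truth, Ct matrix, gene matrix, sheet, predictions."""
    truth = generate_truth(config)
    ct, expr, sheet = generate_expression(truth, config)
    predictions = generate_prediction_table(truth, config)
    return truth, ct, expr, sheet, predictions


# ---------------------------------------------------------------------------
# truth sidecar (JSON) for downstream evaluation


def write_truth_sidecar(truth: RegulatoryTruth, path) -> None:
    payload = {
        "mirna_q": truth.mirna_q,
        "mirna_a": truth.mirna_a,
        "genes_q": truth.genes_q,
        "genes_a": truth.genes_a,
        "genes_bg": truth.genes_bg,
        "true_pairs": sorted(list(p) for p in truth.true_pairs),
        "effects": {f"{m}\t{g}": e for (m, g), e in sorted(truth.effects.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_sidecar(path) -> RegulatoryTruth:
    d = json.loads(Path(path).read_text())
    truth = RegulatoryTruth(
        mirna_q=d["mirna_q"],
        mirna_a=d["mirna_a"],
        genes_q=d["genes_q"],
        genes_a=d["genes_a"],
        genes_bg=d["genes_bg"],
        true_pairs={tuple(p) for p in d["true_pairs"]},
        effects={tuple(k.split("\t")): v for k, v in d.get("effects", {}).items()},
    )
    truth.validate()
    return truth
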