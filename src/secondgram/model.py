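"""Model / Results facade over the training, imputation and evaluation
machinery, in the style of statistical modelling packages: a model object
is built from data, ``fit()`` runs the estimation and returns a results
object carrying the fitted parameters, training diagnostics, a
``summary()`` table, and generation/enrichment/evaluation methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .data import Cohort, SplitCohorts, split_cohort
from .diffusion import NoiseSchedule, make_schedule
from .imputation import enrich_cohort, generate_followup
from .metrics import MetricsReport, covariate_similarity, downstream_auroc, \
    frechet_distance, mean_correlation, paired_similarity
from .network import DenoiserConfig, UNet1D
from .training import GradientPolicy, TrainConfig, TrainHistory, train

__all__ = ["FollowupDiffusion", "FollowupDiffusionResults"]


class FollowupDiffusion:
    """Conditional diffusion model of follow-up imaging features.

    Built from train/validation/test cohorts (all normalized to [-1, 1]);
    ``fit()`` trains the denoiser with self-conditioned samples and
    gradient-manipulated updates and returns a
    :class:`FollowupDiffusionResults`.
    """

    def __init__(self, splits: SplitCohorts,
                 denoiser_config: DenoiserConfig | None = None,
                 schedule: NoiseSchedule | None = None,
                 train_config: TrainConfig | None = None,
                 policy: GradientPolicy | None = None):
        d = splits.train.n_features
        n_l = splits.train.n_labels
        self.splits = splits
        self.denoiser_config = denoiser_config or DenoiserConfig(d=d, n_labels=n_l)
        if self.denoiser_config.d != d or self.denoiser_config.n_labels != n_l:
            raise ValueError("denoiser_config does not match the cohort shape")
        self.schedule = schedule or make_schedule()
        self.train_config = train_config or TrainConfig()
        self.policy = policy or GradientPolicy()

    @classmethod
    def from_cohort(cls, cohort: Cohort, test_frac: float = 0.2,
                    val_frac: float = 0.1, seed: int = 0, **kwargs):
        """Split a single normalized cohort and build the model."""
        splits = split_cohort(cohort, test_frac, val_frac, seed)
        return cls(splits, **kwargs)

    def fit(self, progress: bool = False) -> "FollowupDiffusionResults":
        net, history = train(self.splits, self.denoiser_config,
                             self.train_config, self.policy, self.schedule,
                             progress=progress)
        return FollowupDiffusionResults(self, net, history)

    def config_hash(self) -> str:
        payload = json.dumps({
            "denoiser": self.denoiser_config.to_dict(),
            "schedule": self.schedule.to_dict(),
            "train": asdict(self.train_config),
            "policy": asdict(self.policy),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class FollowupDiffusionResults:
    """Fitted model: parameters, history, and post-estimation tools."""

    def __init__(self, model: FollowupDiffusion, net: UNet1D,
                 history: TrainHistory):
        self.model = model
        self.net = net
        self.history = history

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.net.params

    @property
    def schedule(self) -> NoiseSchedule:
        return self.model.schedule

    def summary(self) -> str:
        h = self.history
        cfg = self.model.train_config
        pol = h.effective_policy or self.model.policy
        rows = [
            ("Epochs run", h.n_epochs),
            ("Best epoch", h.best_epoch + 1),
            ("Best validation score (mean Euclidean)", f"{h.best_score:.4f}"),
            ("Final training loss", f"{h.train_loss[-1]:.4f}" if h.train_loss else "-"),
            ("Clipped updates (total)", sum(h.n_clipped)),
            ("Skipped updates (total)", sum(h.n_skipped)),
            ("Parameters", self.net.n_params),
            ("Self-conditioning", cfg.self_conditioning),
            ("Gradient manipulation", cfg.gradient_manipulation),
            ("Gradient policy",
             f"{pol.mode} ({pol.delta_max:.3g}/{pol.delta_err:.3g})"),
            ("Diffusion steps", self.schedule.T),
            ("Config hash", self.model.config_hash()),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Follow-up diffusion results",
                 "=" * (width + 28)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    # -- generation ------------------------------------------------------
    def generate_followup(self, i1: np.ndarray, l: np.ndarray,
                          seed: int) -> np.ndarray:
        return generate_followup(self.net, i1, l, self.schedule, seed)

    def enrich(self, cohort: Cohort, seed: int) -> Cohort:
        return enrich_cohort(self.net, cohort, self.schedule, seed)

    def generate_for_cohort(self, cohort: Cohort, seed: int) -> np.ndarray:
        """One generated follow-up per record (real follow-ups ignored);
        used for held-out comparison against true follow-ups."""
        from .data import stable_record_seed
        from .diffusion import sample_batch
        I1 = cohort.baseline_matrix()
        L = cohort.labels_matrix()
        seeds = [stable_record_seed(seed, r.patient_id) for r in cohort]
        return sample_batch(self.net.predictor(self.schedule.T), I1, L,
                            self.schedule, seeds, clamp=True)

    # -- evaluation ------------------------------------------------------
    def evaluate(self, test: Cohort | None = None, seed: int = 0,
                 downstream_tasks: list[str] | None = None,
                 reference: Cohort | None = None) -> MetricsReport:
        """Headline metrics on a held-out cohort with real follow-ups.

        Paired similarity compares per-patient generations with real
        follow-ups; distributional metrics compare the generated set with
        the real follow-up set (or an explicit ``reference`` cohort's
        follow-ups); downstream AUROCs train a classifier on the enriched
        training cohort and score it on the test cohort.
        """
        test = test if test is not None else self.model.splits.test
        for rec in test:
            if not rec.has_real_followup:
                raise ValueError(
                    f"evaluation requires real follow-ups; record "
                    f"{rec.patient_id!r} lacks one")
        gen = self.generate_for_cohort(test, seed)
        real = np.stack([r.i2 for r in test])
        sim = paired_similarity(real, gen)
        ref = np.stack([r.i2 for r in reference if r.has_real_followup]) \
            if reference is not None else real
        report = MetricsReport(
            mean_pearson=sim.mean_pearson,
            mean_euclidean=sim.mean_euclidean,
            mean_cosine_distance=sim.mean_cosine_distance,
            frechet=frechet_distance(ref, gen),
            mean_correlation=mean_correlation(ref, gen),
            covariate_similarity=covariate_similarity(ref, gen),
            n_excluded=sim.n_excluded,
        )
        if downstream_tasks:
            enriched = self.enrich(self.model.splits.train, seed)
            report.auroc_by_task = {
                task: downstream_auroc(enriched, test, task, seed=seed)
                for task in downstream_tasks
            }
        return report

    def plot_history(self, ax=None):
        """Training loss and validation score over epochs."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.history.to_dataframe()
        ax.plot(df["epoch"], df["train_loss"], label="training loss")
        ax2 = ax.twinx()
        ax2.plot(df["epoch"], df["val_score"], color="C1",
                 label="validation score")
        ax.set_xlabel("epoch")
        ax.set_ylabel("denoising loss")
        ax2.set_ylabel("validation mean Euclidean")
        ax.axvline(self.history.best_epoch + 1, ls="--", color="grey", lw=0.8)
        return ax

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: parameters + architecture + schedule + config hash."""
        path = Path(path)
        meta = json.dumps({
            "denoiser_config": self.model.denoiser_config.to_dict(),
            "schedule": self.schedule.to_dict(),
            "config_hash": self.model.config_hash(),
            "train_config": asdict(self.model.train_config),
            "policy": asdict(self.model.policy),
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"param::{k}": v for k, v in self.net.params.items()})

    @staticmethod
    def load_net(path: str | Path):
        """Load (UNet1D, NoiseSchedule, meta) from a checkpoint."""
        with np.load(Path(path)) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            params = {k.removeprefix("param::"): f[k]
                      for k in f.files if k.startswith("param::")}
        config = DenoiserConfig.from_dict(meta["denoiser_config"])
        net = UNet1D(config, params=params)
        schedule = NoiseSchedule.from_dict(meta["schedule"])
        net.T = schedule.T
        return net, schedule, meta
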