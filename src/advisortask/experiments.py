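"""Parameter sweeps over agent populations and their summary statistics.

Five canonical simulation sets, each of 972 agents with parameters drawn
independently and uniformly from fixed ranges:

1. no affect, consistently trustworthy advisor
2. with affect, consistently trustworthy advisor
3. no affect, changing trustworthiness
4. with affect, changing trustworthiness
5. with affect, changing trustworthiness, with simulated antipsychotic
   treatment (policy precision halved toward the population minimum after
   an agent's 10th false inference)

Per agent the sweep records task performance, the delusion assessment and
the final habit state; per sweep it reports delusion frequencies at the
main and sensitivity thresholds, Spearman rank correlations of every
parameter with the delusion score and with the proportion of correct card
choices, a standardized regression of delusion score on the parameters and
their pairwise interactions, and decile-averaged state-space trajectories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .generative_model import AgentConfig
from .inference_engine import apply_treatment, run_agent  # noqa: F401 (re-export)
from .task_environment import make_sequence

logger = logging.getLogger("advisortask")

N_AGENTS = 972

#: Uniform sampling ranges for the agent parameters.
PARAM_RANGES = {
    "a": (0.60, 0.99),
    "e0": (2.0, 600.0),
    "initial_consistency": (1, 125),
    "mood": (-4.5, 4.5),
    "alpha": (0.5, 2.75),
    "inv_beta": (0.25, 1.75),
}

INV_BETA_FLOOR = PARAM_RANGES["inv_beta"][0]   # population minimum of 1/beta


@dataclass(frozen=True)
class SweepSpec:
    sequence_kind: str
    affect_enabled: bool
    treatment_enabled: bool = False
    n_agents: int = N_AGENTS
    n_trials: int = 250
    master_seed: int = 0


#: The five canonical simulation sets.
TABLE_SETS = {
    1: dict(sequence_kind="consistently_trustworthy", affect_enabled=False),
    2: dict(sequence_kind="consistently_trustworthy", affect_enabled=True),
    3: dict(sequence_kind="changing_trustworthiness", affect_enabled=False),
    4: dict(sequence_kind="changing_trustworthiness", affect_enabled=True),
    5: dict(sequence_kind="changing_trustworthiness", affect_enabled=True,
            treatment_enabled=True),
}


def sweep_spec_for_set(set_id: int, n_agents: int = N_AGENTS,
                       master_seed: int = 0) -> SweepSpec:
    if set_id not in TABLE_SETS:
        raise ValueError(f"set must be in {sorted(TABLE_SETS)}")
    return SweepSpec(n_agents=n_agents, master_seed=master_seed,
                     **TABLE_SETS[set_id])


@dataclass
class SweepResult:
    spec: SweepSpec
    agents: pd.DataFrame          # one row per agent
    summary: dict
    trajectories: dict            # decile trajectory arrays
    n_failed: int = 0


def sample_parameters(spec: SweepSpec) -> list[dict]:
    """Draw the agent configurations of one sweep.

    Each parameter is uniform over its range; mood is drawn only in affect
    models and the initial-consistency rotation only for the changing
    sequence.  Per-agent seeds derive deterministically from the master
    seed, and the draws do not depend on the treatment flag, so a treated
    sweep with the same master seed is agent-by-agent matched to its
    untreated counterpart.
    """
    rng = np.random.default_rng(spec.master_seed)
    out = []
    for i in range(spec.n_agents):
        params = {
            "a": rng.uniform(*PARAM_RANGES["a"]),
            "e0": rng.uniform(*PARAM_RANGES["e0"]),
            "alpha": rng.uniform(*PARAM_RANGES["alpha"]),
            "inv_beta": rng.uniform(*PARAM_RANGES["inv_beta"]),
            "mood": (rng.uniform(*PARAM_RANGES["mood"])
                     if spec.affect_enabled else 0.0),
            "initial_consistency": (
                int(rng.integers(PARAM_RANGES["initial_consistency"][0],
                                 PARAM_RANGES["initial_consistency"][1] + 1))
                if spec.sequence_kind == "changing_trustworthiness" else 125),
            "agent_seed": int(rng.integers(0, 2**31 - 1)),
            "sequence_seed": int(rng.integers(0, 2**31 - 1)),
        }
        out.append(params)
    return out


def _run_one(params: dict, spec: SweepSpec) -> dict:
    config = AgentConfig(
        likelihood_precision=params["a"],
        habit_resistance=params["e0"],
        mood=params["mood"],
        choice_precision=params["alpha"],
        policy_precision_prior=params["inv_beta"],
        affect_enabled=spec.affect_enabled,
        seed=params["agent_seed"])
    sequence = make_sequence(spec.sequence_kind,
                             initial_consistency=params["initial_consistency"],
                             seed=params["sequence_seed"],
                             n_trials=spec.n_trials)
    records = run_agent(config, sequence, treatment=spec.treatment_enabled)
    assessment = metrics.assess_run(records, spec.sequence_kind)

    choices = np.array([r.choice for r in records])
    cards = np.array([r.correct_card for r in records])
    post = np.array([r.posterior_trust for r in records])
    row = {
        **{k: params[k] for k in ("a", "e0", "mood", "alpha", "inv_beta",
                                  "initial_consistency")},
        "proportion_correct": float((choices == cards).mean()),
        "n_false": int(assessment.false_flags.sum()),
        "falsity": assessment.falsity,
        "certainty_mean": assessment.certainty_mean,
        "certainty_high_share": assessment.certainty_high_share,
        "incorrigibility": assessment.incorrigibility,
        "delusion_score": assessment.delusion_score,
        "habit_strength": assessment.habit_strength,
        "card_habit_delusion": assessment.card_habit_delusion,
        "advisor_habit_delusion": assessment.advisor_habit_delusion,
    }
    for thr in metrics.THRESHOLDS:
        row[f"is_delusion_{thr}"] = assessment.is_delusion[thr]
    traj = {
        "gamma": np.array([r.gamma_T for r in records]),
        "habit_strength": np.array(
            [metrics.habit_strength(r.habit_counts_snapshot) for r in records]),
        "cumulative_change": np.cumsum(np.abs(np.diff(post, prepend=post[0]))),
    }
    return {"row": row, "traj": traj}


def _spearman(x, y) -> float:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _regression(agents: pd.DataFrame, spec: SweepSpec) -> list[dict]:
    """Standardized OLS of delusion score on parameters and all pairwise
    interactions of the standardized parameters."""
    import statsmodels.api as sm

    cols = ["a", "e0", "inv_beta", "alpha"]
    if spec.affect_enabled:
        agents = agents.assign(abs_mood=agents["mood"].abs())
        cols.append("abs_mood")
    if spec.sequence_kind == "changing_trustworthiness":
        cols.append("initial_consistency")
    X = agents[cols].astype(float)
    Xz = (X - X.mean()) / X.std(ddof=0)
    terms = dict(Xz)
    names = list(cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            name = f"{cols[i]}:{cols[j]}"
            terms[name] = Xz[cols[i]] * Xz[cols[j]]
            names.append(name)
    design = pd.DataFrame(terms)
    y = agents["delusion_score"].astype(float)
    yz = (y - y.mean()) / (y.std(ddof=0) or 1.0)
    model = sm.OLS(yz, sm.add_constant(design)).fit()
    out = []
    for name in names:
        out.append({"term": name, "beta": float(model.params[name]),
                    "p_value": float(model.pvalues[name]),
                    "significant": bool(model.pvalues[name] < 0.05)})
    return out


def summarize(agents: pd.DataFrame, spec: SweepSpec) -> dict:
    """Sweep-level summary: delusion frequencies, rank correlations and the
    standardized regression."""
    n = len(agents)
    changing = spec.sequence_kind == "changing_trustworthiness"
    summary = {
        "n_agents": n,
        "sequence_kind": spec.sequence_kind,
        "affect_enabled": spec.affect_enabled,
        "treatment_enabled": spec.treatment_enabled,
        "n_false_inference_agents": int((agents["n_false"] >= 1).sum()),
    }
    for thr in metrics.THRESHOLDS:
        count = int(agents[f"is_delusion_{thr}"].sum())
        summary[f"delusion_count_{thr}"] = count
        summary[f"delusion_frequency_{thr}_pct"] = 100.0 * count / n

    corr_params = ["a", "e0", "alpha", "inv_beta"]
    if spec.affect_enabled:
        corr_params.append("mood")
    if changing:
        corr_params.append("initial_consistency")
    rho_del, rho_correct = {}, {}
    for p in corr_params:
        rho_del[p] = _spearman(agents[p], agents["delusion_score"])
        rho_correct[p] = _spearman(agents[p], agents["proportion_correct"])
    if spec.affect_enabled:
        rho_del["abs_mood"] = _spearman(agents["mood"].abs(),
                                        agents["delusion_score"])
        rho_correct["abs_mood"] = _spearman(agents["mood"].abs(),
                                            agents["proportion_correct"])
    summary["spearman_vs_delusion_score"] = rho_del
    summary["spearman_vs_proportion_correct"] = rho_correct
    summary["spearman_alpha_vs_n_false"] = _spearman(agents["alpha"],
                                                     agents["n_false"])

    # mood analyses restricted to agents with at least one false inference
    if spec.affect_enabled:
        fa = agents[agents["n_false"] >= 1]
        if len(fa) >= 3:
            summary["false_agents_rho_abs_mood_falsity"] = _spearman(
                fa["mood"].abs(), fa["falsity"])
            summary["false_agents_rho_abs_mood_certainty"] = _spearman(
                fa["mood"].abs(), fa["certainty_mean"])

    summary["card_habit_delusion_pct"] = \
        100.0 * float(agents["card_habit_delusion"].mean())
    summary["advisor_habit_delusion_pct"] = \
        100.0 * float(agents["advisor_habit_delusion"].mean())
    try:
        summary["regression"] = _regression(agents, spec)
    except Exception as err:  # degenerate designs on tiny smoke sweeps
        logger.warning("regression skipped: %s", err)
        summary["regression"] = []
    return summary


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run every agent of a sweep and summarize.

    Individual agent failures are logged and excluded; the sweep aborts if
    more than 1% of agents fail.
    """
    params = sample_parameters(spec)
    rows, trajs = [], []
    n_failed = 0
    for i, p in enumerate(params):
        try:
            res = _run_one(p, spec)
        except Exception as err:
            n_failed += 1
            logger.warning("agent %d failed: %s", i, err)
            if n_failed > max(1, 0.01 * spec.n_agents):
                raise RuntimeError(
                    f"more than 1% of agents failed ({n_failed})") from err
            continue
        rows.append(res["row"])
        trajs.append(res["traj"])
    agents = pd.DataFrame(rows)
    summary = summarize(agents, spec)
    if len(agents) >= 10:
        trajectories = metrics.decile_trajectories(
            agents["falsity"].to_numpy(),
            np.stack([t["gamma"] for t in trajs]),
            np.stack([t["habit_strength"] for t in trajs]),
            np.stack([t["cumulative_change"] for t in trajs]))
    else:
        trajectories = {}
    return SweepResult(spec=spec, agents=agents, summary=summary,
                       trajectories=trajectories, n_failed=n_failed)


def write_report(result: SweepResult, out_dir, plots: bool = False) -> dict:
    """Write the sweep artifacts: summary JSON/CSV, per-agent CSV, long-format
    decile trajectory CSV and (optionally) diagnostic plots.

    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = dict(result.summary)
    summary["master_seed"] = result.spec.master_seed
    summary["n_failed"] = result.n_failed
    for thr in metrics.THRESHOLDS:
        summary[f"delusion_frequency_{thr}_formatted"] = \
            f"{summary[f'delusion_frequency_{thr}_pct']:.1f}%"
    paths["summary_json"] = out / "summary.json"
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    flat = {k: v for k, v in summary.items()
            if not isinstance(v, (dict, list))}
    for group in ("spearman_vs_delusion_score", "spearman_vs_proportion_correct"):
        for p, rho in summary[group].items():
            flat[f"{group}.{p}"] = rho
    paths["summary_csv"] = out / "summary.csv"
    pd.DataFrame([flat]).to_csv(paths["summary_csv"], index=False)

    paths["agents_csv"] = out / "agents.csv"
    result.agents.to_csv(paths["agents_csv"], index=False)

    if result.trajectories:
        rows = []
        for var in ("gamma", "habit_strength", "cumulative_change"):
            arr = result.trajectories[var]
            for dec in range(arr.shape[0]):
                for trial in range(arr.shape[1]):
                    rows.append({"decile": dec + 1, "trial": trial,
                                 "variable": var,
                                 "value": arr[dec, trial]})
        paths["trajectories_csv"] = out / "trajectories.csv"
        pd.DataFrame(rows).to_csv(paths["trajectories_csv"], index=False)

    if plots and result.trajectories:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, var in zip(axes, ("gamma", "habit_strength",
                                  "cumulative_change")):
            for dec in range(10):
                ax.plot(result.trajectories[var][dec], lw=0.8)
            ax.set_title(var)
            ax.set_xlabel("trial")
        fig.tight_layout()
        paths["trajectories_png"] = out / "trajectories.png"
        fig.savefig(paths["trajectories_png"], dpi=120)
        plt.close(fig)
    return paths
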