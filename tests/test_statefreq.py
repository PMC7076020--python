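import numpy as np
import pandas as pd
import pytest

from mweeg.statefreq import SingularDesignError, omnibus_glm, posthoc_contrasts, tabulate
from mweeg.stats import bh_adjust
from mweeg.synth import (
    SynthConfig,
    make_participants,
    null_config,
    simulate_responses,
    simulate_study,
)


def brute_force_bh(p):
    """Independent step-up oracle: adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def responses_frame(cfg, seed):
    parts = make_participants(cfg)
    rows = []
    for p in parts:
        for r in simulate_responses(p, cfg, seed=seed):
            rows.append({"participant_id": p.id, "group": p.group,
                         "synchrony": r.synchrony, "answer": r.answer})
    return pd.DataFrame(rows)


def test_tabulate_explicit_zero_cells():
    resp = pd.DataFrame({
        "participant_id": ["P01"] * 10, "group": ["CTRL"] * 10,
        "synchrony": ["Sync"] * 10, "answer": ["MW"] * 10,
    })
    table = tabulate(resp)
    assert len(table) == 4  # all four answers materialized
    mw = table[table.answer == "MW"].iloc[0]
    assert mw["count"] == 10 and mw["n_probes"] == 10
    assert table[table.answer != "MW"]["count"].tolist() == [0, 0, 0]


def test_tabulate_empty_input():
    assert len(tabulate(pd.DataFrame(columns=["participant_id", "group",
                                              "synchrony", "answer"]))) == 0


def test_tabulate_rejects_unknown_answer():
    resp = pd.DataFrame({"participant_id": ["P01"], "group": ["CTRL"],
                         "synchrony": ["Sync"], "answer": ["Bored"]})
    with pytest.raises(ValueError, match="unknown answers"):
        tabulate(resp)


def test_tabulate_counts_sum_to_probes(study_cfg):
    table = tabulate(responses_frame(study_cfg, seed=1))
    sums = table.groupby(["participant_id", "synchrony"]).agg(
        total=("count", "sum"), n=("n_probes", "first"))
    assert (sums["total"] == sums["n"]).all()


def test_relative_frequencies_match_generator_probs():
    """At many probes per cell, relative frequencies approach the multinomial p."""
    cfg = null_config(n_ctrl=200, n_szq=0)
    table = tabulate(responses_frame(cfg, seed=2))
    probs = dict(zip(("Audio", "Image", "Full", "MW"),
                     cfg.answer_probs[("CTRL", "Sync")]))
    cell = table[table.synchrony == "Sync"].groupby("answer")["rel_freq"].mean()
    n_eff = table[table.synchrony == "Sync"]["n_probes"].iloc[0] * 200
    for answer, p in probs.items():
        se = np.sqrt(p * (1 - p) / n_eff)
        assert cell[answer] == pytest.approx(p, abs=4 * se)


def test_omnibus_df_pattern(study_cfg):
    table = tabulate(responses_frame(study_cfg, seed=3))
    res = omnibus_glm(table)
    assert res["df"].tolist() == [1, 3, 1, 3, 1, 3, 3]
    assert res["effect"].tolist() == [
        "Group", "Cognitive State", "Synchrony", "Group x Cognitive State",
        "Group x Synchrony", "Synchrony x Cognitive State",
        "Group x Synchrony x Cognitive State",
    ]


def test_omnibus_group_null_when_groups_identical(study_cfg):
    table = tabulate(responses_frame(study_cfg, seed=4))
    ctrl = table[table.group == "CTRL"].copy()
    clone = ctrl.copy()
    clone["group"] = "SZQ"
    clone["participant_id"] = clone["participant_id"] + "x"
    res = omnibus_glm(pd.concat([ctrl, clone], ignore_index=True))
    group_chi2 = res.loc[res.effect == "Group", "wald_chi2"].iloc[0]
    assert group_chi2 < 1e-10


def test_omnibus_singular_design_names_cells(study_cfg):
    table = tabulate(responses_frame(study_cfg, seed=5))
    table.loc[(table.group == "SZQ") & (table.answer == "Audio"), "count"] = 0
    with pytest.raises(SingularDesignError, match="Audio"):
        omnibus_glm(table)


def test_posthoc_identical_groups_null(study_cfg):
    table = tabulate(responses_frame(study_cfg, seed=6))
    ctrl = table[table.group == "CTRL"].copy()
    clone = ctrl.copy()
    clone["group"] = "SZQ"
    clone["participant_id"] = clone["participant_id"] + "x"
    res = posthoc_contrasts(pd.concat([ctrl, clone], ignore_index=True))
    assert len(res) == 8
    assert np.allclose(res["t"], 0.0, atol=1e-12)
    assert np.allclose(res["p_adj"], 1.0)


def test_bh_matches_brute_force_oracle(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 12))
        p = rng.uniform(size=m)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_bh_hand_example():
    """p=(.01,.02,.03,.04), m=4: step-up collapses all to 0.04."""
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_null_family_wise_bh_rate(null_cfg):
    """Null generator: any BH-significant contrast in at most ~5% of replicates."""
    n_rep = 400
    any_sig = 0
    for rep in range(n_rep):
        table = tabulate(responses_frame(null_cfg, seed=10_000 + rep))
        res = posthoc_contrasts(table)
        any_sig += bool((res["p_adj"] < 0.05).any())
    assert any_sig / n_rep <= 0.07


def test_mw_contrast_power(study_cfg):
    """Default generator (elevated MW in SZQ): both MW contrasts detected."""
    n_rep = 100
    mw_both = 0
    for rep in range(n_rep):
        table = tabulate(responses_frame(study_cfg, seed=20_000 + rep))
        post = posthoc_contrasts(table)
        mw = post[post.answer == "MW"]
        mw_both += bool((mw["p_adj"] < 0.05).all())
    assert mw_both / n_rep > 0.8


def test_power_injected_three_way_effect():
    """A group x synchrony swap of Full/MW rates is detected by the omnibus Wald."""
    cfg = null_config()
    probs = dict(cfg.answer_probs)
    probs[("CTRL", "Sync")] = (0.10, 0.10, 0.50, 0.30)
    probs[("CTRL", "NoSync")] = (0.10, 0.10, 0.30, 0.50)
    probs[("SZQ", "Sync")] = (0.10, 0.10, 0.30, 0.50)
    probs[("SZQ", "NoSync")] = (0.10, 0.10, 0.50, 0.30)
    cfg = SynthConfig(hurst_by_cell=cfg.hurst_by_cell, answer_probs=probs)
    n_rep = 200
    three_way = 0
    for rep in range(n_rep):
        table = tabulate(responses_frame(cfg, seed=30_000 + rep))
        res = omnibus_glm(table)
        p3 = res.loc[res.effect == "Group x Synchrony x Cognitive State", "p"].iloc[0]
        three_way += p3 < 0.05
    assert three_way / n_rep > 0.5
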