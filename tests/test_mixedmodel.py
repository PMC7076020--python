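import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mweeg.mixedmodel import (
    DesignLevelError,
    MixedSpec,
    fit_mixed_anova,
    levene_check,
    simple_effects,
)
from mweeg.montage import REGIONS
from mweeg.synth import SynthConfig, make_participants, null_config, simulate_hfd_records


def records_for(cfg):
    return simulate_hfd_records(make_participants(cfg), cfg)


@pytest.fixture(scope="module")
def default_fit(study_cfg):
    records = records_for(study_cfg)
    effects, model = fit_mixed_anova(records)
    return records, effects, model


def test_fifteen_effect_rows(default_fit):
    _, effects, _ = default_fit
    assert len(effects) == 15
    assert effects["df_num"].tolist() == [1, 1, 1, 9,  # mains
                                          1, 1, 9, 1, 9, 9,  # two-way
                                          1, 9, 9, 9,  # three-way
                                          9]  # four-way
    assert effects["effect"].iloc[0] == "Group"
    assert effects["effect"].iloc[-1] == "Group x Answer x Synchrony x Area"


def test_injected_interaction_detected(default_fit):
    """The CTRL/Sync-only MW-Full gap shows up in Group x Answer x Synchrony."""
    _, effects, _ = default_fit
    row = effects[effects["effect"] == "Group x Answer x Synchrony"].iloc[0]
    assert row["p"] < 0.05


def test_simple_effect_pattern(default_fit):
    """MW-Full elevations concentrate where injected: CTRL, Sync, non-occipital."""
    _, _, model = default_fit
    se = simple_effects(model)
    assert len(se) == 40
    ctrl_sync = se[(se.group == "CTRL") & (se.synchrony == "Sync")]
    non_op = ctrl_sync[~ctrl_sync.area.isin(["OP", "OPL", "OPR"])]
    assert (non_op["estimate"] > 0).all()
    assert non_op["estimate"].mean() == pytest.approx(0.03, abs=0.02)


def test_missing_level_raises(study_cfg):
    records = records_for(study_cfg)
    with pytest.raises(DesignLevelError, match="area"):
        fit_mixed_anova(records[records["area"] != "Pz_missing_ok"].query("area != 'F'"))


def test_answers_other_than_mw_full_excluded(default_fit):
    records, _, model = default_fit
    assert set(model.data["answer"]) == {"MW", "Full"}
    assert len(model.data) < len(records)


def test_satterthwaite_df_plausible(default_fit):
    """Within-participant effects get close-to-residual dfs; Group gets ~n-2."""
    _, effects, _ = default_fit
    group_df = effects.loc[effects["effect"] == "Group", "df_den"].iloc[0]
    answer_df = effects.loc[effects["effect"] == "Answer", "df_den"].iloc[0]
    assert 30 < group_df < 60
    assert answer_df > 1000


def test_agrees_with_lmerTest_oracle(tmp_path):
    """Independent oracle: lme4/lmerTest reproduces F, df and variances."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the mixed-model oracle")
    cfg = SynthConfig(n_ctrl=5, n_szq=5, seed=17)
    records = records_for(cfg)
    effects, model = fit_mixed_anova(records)
    csv = tmp_path / "rec.csv"
    records.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lmerTest))
        d <- read.csv('{csv}')
        d <- d[d$answer %in% c('MW','Full'),]
        for (c in c('group','answer','synchrony','area')) {{
            d[[c]] <- factor(d[[c]]); contrasts(d[[c]]) <- contr.sum
        }}
        m <- lmer(hfd ~ group*answer*synchrony*area + (1|participant_id),
                  data=d, REML=TRUE)
        a <- anova(m, type=3, ddf='Satterthwaite')
        out <- data.frame(term=rownames(a), F=a$`F value`, df=a$DenDF)
        write.csv(out, '{tmp_path}/anova.csv', row.names=FALSE)
        vc <- as.data.frame(VarCorr(m))
        write.csv(vc[,c('grp','sdcor')], '{tmp_path}/vc.csv', row.names=FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_anova = pd.read_csv(tmp_path / "anova.csv")
    r_vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["sdcor"]

    key = {t: (t.replace("group", "Group").replace("answer", "Answer")
               .replace("synchrony", "Synchrony").replace("area", "Area")
               .replace(":", " x ")) for t in r_anova["term"]}
    ours = effects.set_index("effect")
    for term, row in r_anova.set_index("term").iterrows():
        mine = ours.loc[key[term]]
        assert mine["F"] == pytest.approx(row["F"], rel=1e-4)
        assert mine["df_den"] == pytest.approx(row["df"], rel=0.05)
    assert np.sqrt(model.sigma_b2) == pytest.approx(r_vc["participant_id"], rel=1e-3)
    assert np.sqrt(model.sigma_e2) == pytest.approx(r_vc["Residual"], rel=1e-3)


def _balanced_records(rng, n_participants=12, sd_b=0.05, sd_e=0.05, mu=1.5):
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        group = "CTRL" if i < n_participants // 2 else "SZQ"
        b = rng.normal(0, sd_b)
        for sync in ("Sync", "NoSync"):
            for answer in ("MW", "Full"):
                for area in REGIONS:
                    rows.append({"participant_id": pid, "group": group,
                                 "synchrony": sync, "answer": answer,
                                 "area": area,
                                 "hfd": mu + b + rng.normal(0, sd_e)})
    return pd.DataFrame(rows)


def test_type_three_equals_type_one_on_balanced_data(rng):
    """With equal cell counts the sequential and marginal F coincide."""
    records = _balanced_records(rng)
    effects, model = fit_mixed_anova(records)
    t1 = model.anova_type1().set_index("effect")
    for _, row in effects.iterrows():
        assert row["F"] == pytest.approx(t1.loc[row["effect"], "F"], abs=1e-8)


def test_wald_contrast_matches_dense_gls_closed_form(rng):
    """The profiled Sherman-Morrison algebra matches brute-force dense GLS.

    At the fitted variance components, beta, the contrast estimate and the
    Wald statistic are recomputed with explicit dense V = sigma_e^2 I +
    sigma_b^2 ZZ' and plain numpy solves; balanced single-area design, so
    the contrast estimate must also equal the raw cell-mean difference.
    """
    import patsy

    rows = []
    for i in range(16):
        pid = f"P{i + 1:02d}"
        group = "CTRL" if i < 8 else "SZQ"
        for sync in ("Sync", "NoSync"):
            for answer in ("MW", "Full"):
                rows.append({"participant_id": pid, "group": group,
                             "synchrony": sync, "answer": answer, "area": "F",
                             "hfd": 1.5 + 0.05 * (answer == "MW")
                             + rng.normal(0, 0.05)})
    records = pd.DataFrame(rows)
    spec = MixedSpec(areas=("F",))
    effects, model = fit_mixed_anova(records, spec)

    X = patsy.dmatrix("C(group, Sum) * C(answer, Sum) * C(synchrony, Sum)",
                      records, return_type="dataframe")
    Xm = X.to_numpy()
    y = records["hfd"].to_numpy()
    Z = pd.get_dummies(records["participant_id"]).to_numpy(dtype=float)
    V = model.sigma_e2 * np.eye(len(y)) + model.sigma_b2 * Z @ Z.T
    Vinv = np.linalg.inv(V)
    C = np.linalg.inv(Xm.T @ Vinv @ Xm)
    beta = C @ Xm.T @ Vinv @ y
    frame = pd.DataFrame({"group": ["CTRL", "CTRL"], "answer": ["MW", "Full"],
                          "synchrony": ["Sync", "Sync"]})
    (rowmat,) = patsy.build_design_matrices([X.design_info], frame)
    l = np.asarray(rowmat)[0] - np.asarray(rowmat)[1]
    expected_est = float(l @ beta)
    expected_chi2 = expected_est**2 / float(l @ C @ l)

    se = simple_effects(model, spec)
    got = se[(se.group == "CTRL") & (se.synchrony == "Sync")].iloc[0]
    assert got["estimate"] == pytest.approx(expected_est, abs=1e-10)
    assert got["wald_chi2"] == pytest.approx(expected_chi2, rel=1e-6)
    # balanced design: model cell-mean difference = raw cell-mean difference
    cell = records[(records.group == "CTRL") & (records.synchrony == "Sync")]
    raw_diff = (cell[cell.answer == "MW"]["hfd"].mean()
                - cell[cell.answer == "Full"]["hfd"].mean())
    assert got["estimate"] == pytest.approx(raw_diff, abs=1e-10)


def test_null_f_statistics_center_near_one(null_cfg):
    fs = []
    for rep in range(12):
        cfg = SynthConfig(hurst_by_cell=null_cfg.hurst_by_cell,
                          answer_probs=null_cfg.answer_probs, seed=100 + rep)
        effects, _ = fit_mixed_anova(records_for(cfg))
        fs.extend(effects["F"])
    assert np.mean(fs) == pytest.approx(1.0, abs=0.25)


def test_parameter_and_variance_recovery(study_cfg):
    """Injected MW-Full gap and the participant SD are recovered across replicates.

    The generating gap (0.03 in CTRL/Sync non-occipital areas) should lie
    within 2 SE of its estimate in >= 90% of replicates, and the median
    estimated between-participant SD should land within 25% of truth.
    """
    n_rep = 40
    hits = 0
    sds = []
    for rep in range(n_rep):
        cfg = SynthConfig(seed=500 + rep)
        effects, model = fit_mixed_anova(records_for(cfg))
        se = simple_effects(model)
        row = se[(se.group == "CTRL") & (se.synchrony == "Sync")
                 & (se.area == "F")].iloc[0]
        stderr = abs(row["estimate"]) / np.sqrt(row["wald_chi2"])
        hits += abs(row["estimate"] - 0.03) <= 2 * stderr
        sds.append(np.sqrt(model.sigma_b2))
    assert hits / n_rep >= 0.9
    assert np.median(sds) == pytest.approx(study_cfg.hfd_participant_sd, rel=0.25)


def test_levene_df_contract():
    """80 cells and 6370 records give Brown-Forsythe dfs (79, 6290)."""
    rng = np.random.default_rng(0)
    sizes = np.full(80, 6370 // 80)
    sizes[: 6370 - sizes.sum()] += 1
    rows = []
    i = 0
    for g in ("CTRL", "SZQ"):
        for s in ("Sync", "NoSync"):
            for a in ("MW", "Full"):
                for area in REGIONS:
                    rows.append(pd.DataFrame({
                        "participant_id": "P01", "group": g, "synchrony": s,
                        "answer": a, "area": area,
                        "hfd": rng.normal(1.5, 0.05, sizes[i])}))
                    i += 1
    records = pd.concat(rows, ignore_index=True)
    out = levene_check(records)
    assert (out["df1"], out["df2"]) == (79, 6290)
    assert out["n_records"] == 6370


def test_levene_null_calibration(rng):
    rejections = 0
    n_rep = 60
    for _ in range(n_rep):
        records = pd.DataFrame({
            "participant_id": "P01",
            "group": np.repeat(["CTRL", "SZQ"], 2000),
            "synchrony": np.tile(np.repeat(["Sync", "NoSync"], 1000), 2),
            "answer": np.tile(np.repeat(["MW", "Full"], 500), 4),
            "area": np.tile(np.repeat(REGIONS, 50), 8),
            "hfd": rng.normal(1.5, 0.05, 4000),
        })
        rejections += levene_check(records)["p"] < 0.05
    assert rejections / n_rep <= 0.10


def test_levene_detects_heteroscedasticity(rng):
    for _ in range(5):
        sd = np.repeat([0.05, 0.10], 3000)  # one group twice as variable
        records = pd.DataFrame({
            "participant_id": "P01",
            "group": np.repeat(["CTRL", "SZQ"], 3000),
            "synchrony": np.tile(np.repeat(["Sync", "NoSync"], 1500), 2),
            "answer": np.tile(np.repeat(["MW", "Full"], 750), 4),
            "area": np.tile(np.repeat(REGIONS, 75), 8),
            "hfd": rng.normal(1.5, sd),
        })
        assert levene_check(records)["p"] < 0.05
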