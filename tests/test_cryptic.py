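"""Constitutive-vs-cryptic second stage: geometry, U1 profiles, shuffled-PWM
controls."""

import numpy as np
import pytest

from cpascan.cryptic import (
    CrypticModelError,
    CrypticStageConfig,
    build_cryptic_matrix,
    recenter_window,
    shuffle_control,
    train_cryptic_model,
    u1_positional_profile,
)
from cpascan.datasets import LabeledWindow, build_cryptic_set
from cpascan.features import parse_feature_name
from cpascan.models import ModelConfig, top_k_features, train
from cpascan.motifs import (
    PWM,
    Splice5Scorer,
    U1DuplexScorer,
    pwm_from_consensus,
    synthetic_rbp_panel,
)
from cpascan.scan import scan_gene
from cpascan.sequence_io import GenomicInterval, extract_window
from cpascan.simulate import GeneratorSpec, generate


def _window(seq, label, gene="G"):
    return LabeledWindow(
        gene, GenomicInterval("chr1", 1000, 1000 + len(seq), "+"), seq, label,
        site_offset=len(seq) // 2,
    )


@pytest.fixture(scope="module")
def stage_windows(truth, registry, lr_model, splits):
    """Site-centred 140 nt windows: constitutive positives recentred, cryptic
    windows called from scanned training genes."""
    gms = truth.gene_models()
    gene_ids = sorted({w.gene_id for w in splits["pos_train"]})[:40]
    tracks = [scan_gene(lr_model, gms[g], truth.sequences, registry) for g in gene_ids]
    cryptic500 = build_cryptic_set(tracks, truth.all_known_sites, truth.sequences)
    const = [recenter_window(w) for w in splits["pos_train"][:80]]
    cryp = [recenter_window(w) for w in cryptic500]
    assert len(cryp) >= 40
    return const, cryp


class TestConfigAndMatrix:
    def test_column_count_law(self):
        cfg = CrypticStageConfig(rbp_pwms=synthetic_rbp_panel(12))
        assert cfg.grid.n_bins == 13
        assert cfg.n_columns == (2 + 12) * 13

    def test_u1_only_columns(self):
        cfg = CrypticStageConfig(rbp_pwms=[])
        assert cfg.n_columns == 2 * 13 == 26

    def test_no_representations_rejected(self):
        with pytest.raises(CrypticModelError):
            CrypticStageConfig(u1_scorers=(), rbp_pwms=[])

    def test_matrix_shape_and_labels(self, stage_windows):
        const, cryp = stage_windows
        cfg = CrypticStageConfig(rbp_pwms=synthetic_rbp_panel(12))
        m = build_cryptic_matrix(const[:10], cryp[:10], cfg)
        assert m.values.shape == (20, 14 * 13)
        assert (m.labels[:10] == "constitutive").all()
        assert (m.labels[10:] == "cryptic").all()

    def test_wrong_window_length_rejected(self):
        cfg = CrypticStageConfig(rbp_pwms=synthetic_rbp_panel(3))
        with pytest.raises(Exception):
            build_cryptic_matrix([_window("A" * 100, "positive")], [], cfg)

    def test_recenter_geometry(self, splits):
        w = splits["pos_train"][0]
        r = recenter_window(w, 70)
        assert len(r.sequence) == 140
        assert r.site_offset == 70
        assert r.sequence == w.sequence[180:320]


class TestU1Profile:
    def test_identical_windows_zero_spread(self):
        win = "ACGUACGUACGUACGUACGU"
        med, sd = u1_positional_profile([win] * 5, U1DuplexScorer())
        assert np.allclose(sd, 0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(CrypticModelError):
            u1_positional_profile([], U1DuplexScorer())

    def test_planted_u1_enriches_decoy_profile(self):
        """With the generator's U1-planting option on, the 5'SS score
        profile upstream of decoy (cryptic-like) sites exceeds the
        constitutive-site profile."""
        t = generate(
            GeneratorSpec(n_genes=60, plant_u1_near_decoys=True,
                          decoy_rate_per_kb=0.5, decoy_policy="pas_only", seed=0)
        )
        scorer = Splice5Scorer()
        const = [
            extract_window(t.sequences, s.position, 70)
            for s in list(t.constitutive_sites.values())[:50]
        ]
        decoy = [extract_window(t.sequences, d.position, 70) for d in t.decoys[:50]]
        m_const, _ = u1_positional_profile(const, scorer)
        m_decoy, _ = u1_positional_profile(decoy, scorer)
        upstream = slice(0, 60)
        assert m_decoy[upstream].mean() > m_const[upstream].mean()


class TestShuffleControl:
    def _config(self, n_pwms=6, **kw):
        return CrypticStageConfig(rbp_pwms=synthetic_rbp_panel(n_pwms), **kw)

    def test_five_shuffles_returned(self, stage_windows):
        const, cryp = stage_windows
        cfg = self._config()
        half_c, half_k = len(const) // 2, len(cryp) // 2
        res = shuffle_control(
            const[:half_c], cryp[:half_k], const[half_c:], cryp[half_k:], cfg
        )
        assert len(res["shuffles"]) == 5
        for r in [res["original"], *res["shuffles"]]:
            assert 0.0 <= r.auroc <= 1.0

    def test_deterministic(self, stage_windows):
        const, cryp = stage_windows
        cfg = self._config(n_pwms=4)
        args = (const[:30], cryp[:20], const[30:60], cryp[20:40], cfg)
        a = shuffle_control(*args)
        b = shuffle_control(*args)
        assert a["original"].auroc == b["original"].auroc
        assert [r.auroc for r in a["shuffles"]] == [r.auroc for r in b["shuffles"]]

    def test_length_one_pwms_shuffle_to_identity(self, stage_windows):
        const, cryp = stage_windows
        single = [
            PWM("mono_u", np.array([[0.1, 0.1, 0.1, 0.7]])),
            PWM("mono_g", np.array([[0.1, 0.1, 0.7, 0.1]])),
        ]
        cfg = CrypticStageConfig(rbp_pwms=single, n_shuffles=2)
        res = shuffle_control(const[:30], cryp[:20], const[30:60], cryp[20:40], cfg)
        for r in res["shuffles"]:
            assert r.auroc == pytest.approx(res["original"].auroc)

    def test_l1_sparsity_ladder_on_stage_two(self, stage_windows):
        """The cryptic-stage strength 0.0018 never keeps more features than
        the baseline strength 0.1 on identical data."""
        const, cryp = stage_windows
        cfg = self._config()
        m = build_cryptic_matrix(const, cryp, cfg)
        nnz = {}
        for C in (0.0018, 0.1):
            model = train(ModelConfig.linear(C=C, seed=0), m,
                          positive_label="constitutive")
            coefs = np.array(list(model.feature_importances.values()))
            nnz[C] = int((coefs != 0).sum())
        assert nnz[0.0018] <= nnz[0.1]

    def test_missing_pas_decoys_put_top_weights_in_central_bins(self):
        """When cryptic decoys carry everything except the PAS, the most
        informative stage-two features concentrate in the central bins
        around the PAS position (the synthetic analogue of PAS-like motifs
        dominating the real constitutive-vs-cryptic model)."""
        t = generate(
            GeneratorSpec(n_genes=120, decoy_policy="no_pas",
                          decoy_rate_per_kb=0.6, alt_site_prob=0.0, seed=0)
        )
        const = [
            _window(extract_window(t.sequences, s.position, 70), "unlabeled", s.gene_id)
            for s in t.constitutive_sites.values()
        ]
        decoy = [
            _window(extract_window(t.sequences, d.position, 70), "unlabeled", d.gene_id)
            for d in t.decoys
        ]
        cfg = CrypticStageConfig(rbp_pwms=synthetic_rbp_panel(12), lr_strength=0.1)
        model = train_cryptic_model(const, decoy, cfg)
        imp = model.feature_importances
        ranked = sorted(imp, key=lambda n: -abs(imp[n]))
        # PAS sits at offsets ~38-46 of the 140 nt window: bins 2-5.  The
        # two dominant coefficients are the PAS-like motif in those bins,
        # well clear of the remaining (noise) features.
        for name in ranked[:2]:
            rep, bin_idx, _, _ = parse_feature_name(name)
            assert rep == "panel_pas_like"
            assert 2 <= bin_idx <= 5
        assert abs(imp[ranked[1]]) > 3 * abs(imp[ranked[2]])
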