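"""PDB reading, region configs, membrane axis and residue projection."""

import numpy as np
import pytest

from ckrdiv.structure import (
    ChainNotFoundError,
    DegenerateAxisError,
    InsertionCodeError,
    ProjectionAxis,
    RegionConfig,
    StructureModel,
    compute_axis,
    project_residues,
    read_structure,
    tm_center_distance,
    write_ca_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.000   8.000   9.000  1.00  0.00           C
HETATM    5  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C
END
"""

ICODE_PDB = """\
ATOM      1  CA  ALA A   1A      1.000   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_trace(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path, "A")
        assert list(model.residues) == [1, 2, 3]
        assert np.allclose(model.residues[1], [1, 2, 3])
        assert np.allclose(model.residues[3], [7, 8, 9])

    def test_missing_chain(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(ChainNotFoundError):
            read_structure(path, "Z")

    def test_first_altloc_kept(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path, "A")
        assert model.residues[1][0] == pytest.approx(1.0)

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(ICODE_PDB)
        with pytest.raises(InsertionCodeError):
            read_structure(path, "A")

    def test_residue_without_ca_skipped_with_warning(self, tmp_path):
        text = MINIMAL_PDB.replace(
            "ATOM      2  CA  ALA", "ATOM      2  CB  ALA"
        )
        path = tmp_path / "noca.pdb"
        path.write_text(text)
        with pytest.warns(UserWarning, match="no C-alpha"):
            model = read_structure(path, "A")
        assert list(model.residues) == [2, 3]

    def test_write_read_round_trip(self, tmp_path):
        model = StructureModel(
            residues={1: np.array([1.234, -5.678, 9.012]), 7: np.array([0.0, 0.5, -0.5])}
        )
        path = tmp_path / "rt.pdb"
        write_ca_pdb(model, path)
        back = read_structure(path, "A")
        for r in model.residues:
            assert np.allclose(back.residues[r], model.residues[r], atol=1e-3)


def _slab_model_and_cfg(translate=(0.0, 0.0, 0.0)):
    """4 extracellular CAs at z=+10, 4 intracellular at z=-10, 2 TM at 0."""
    t = np.asarray(translate, dtype=float)
    coords = {}
    for i in range(4):
        coords[i + 1] = np.array([float(i), 0.0, 10.0]) + t       # N/ECL side
    coords[5] = np.array([1.5, 0.0, 5.0]) + t                      # TM1
    coords[6] = np.array([1.5, 0.0, -5.0]) + t                     # TM1
    for i in range(4):
        coords[i + 7] = np.array([float(i), 0.0, -10.0]) + t       # ICL side
    cfg = RegionConfig(
        ranges={"N": (1, 4), "TM1": (5, 6), "ICL1": (7, 10)},
    )
    return StructureModel(residues=coords), cfg


class TestAxisAndProjection:
    def test_symmetric_slab_axis(self):
        model, cfg = _slab_model_and_cfg()
        axis = compute_axis(model, cfg)
        assert np.allclose(axis.midpoint, [1.5, 0, 0])
        assert np.allclose(axis.unit_vector, [0, 0, 1])

    def test_translation_equivariance(self):
        model, cfg = _slab_model_and_cfg(translate=(5, 5, 5))
        axis = compute_axis(model, cfg)
        assert np.allclose(axis.midpoint, [6.5, 5, 5])
        assert np.allclose(axis.unit_vector, [0, 0, 1])

    def test_degenerate_axis(self):
        coords = {1: np.zeros(3), 2: np.zeros(3)}
        cfg = RegionConfig(ranges={"N": (1, 1), "ICL1": (2, 2)})
        with pytest.raises(DegenerateAxisError):
            compute_axis(StructureModel(residues=coords), cfg)

    def test_projection_scores(self):
        axis = ProjectionAxis(
            center_extra=np.array([0.0, 0.0, 10.0]),
            center_intra=np.array([0.0, 0.0, -10.0]),
        )
        coords = {
            1: np.array([0.0, 0.0, 0.0]),    # at midpoint
            2: np.array([0.0, 0.0, 4.0]),    # straight up
            3: np.array([3.0, 4.0, -2.0]),   # lateral offset ignored
        }
        cfg = RegionConfig(ranges={"N": (1, 3)})
        proj = project_residues(StructureModel(residues=coords), axis, cfg)
        assert proj.score_of[1] == pytest.approx(0.0)
        assert proj.score_of[2] == pytest.approx(4.0)
        assert proj.score_of[3] == pytest.approx(-2.0)

    def test_excluded_residues_not_projected_cterm_is(self):
        model, cfg = _slab_model_and_cfg()
        cfg2 = RegionConfig(
            ranges=cfg.ranges | {"C": (9, 10)},
            excluded_ranges=((4, 4),),
            cterm_range=(9, 10),
        )
        # C-term removed from the intracellular center...
        axis = compute_axis(model, cfg2)
        assert np.allclose(axis.center_intra, np.mean([[0, 0, -10], [1, 0, -10]], axis=0))
        # ...but its residues still get projection scores; excluded ones do not
        proj = project_residues(model, axis, cfg2)
        assert 9 in proj.score_of and 10 in proj.score_of
        assert 4 not in proj.score_of

    def test_axis_score_of_centers(self):
        model, cfg = _slab_model_and_cfg()
        axis = compute_axis(model, cfg)
        proj_extra = float(axis.unit_vector @ (axis.center_extra - axis.midpoint))
        proj_intra = float(axis.unit_vector @ (axis.center_intra - axis.midpoint))
        half = np.linalg.norm(axis.center_extra - axis.center_intra) / 2
        assert proj_extra == pytest.approx(half)
        assert proj_intra == pytest.approx(-half)


class TestTMCenterDistance:
    def test_symmetric_bundle_zero(self):
        model, cfg = _slab_model_and_cfg()
        axis = compute_axis(model, cfg)
        assert tm_center_distance(model, axis, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_bundle(self):
        model, cfg = _slab_model_and_cfg()
        shifted = dict(model.residues)
        shifted[5] = shifted[5] + np.array([0, 0, 1.0])
        shifted[6] = shifted[6] + np.array([0, 0, 1.0])
        model2 = StructureModel(residues=shifted)
        axis = compute_axis(model2, cfg)
        assert tm_center_distance(model2, axis, cfg) == pytest.approx(1.0)

    def test_no_tm_residues(self):
        coords = {1: np.zeros(3), 2: np.array([0.0, 0.0, 1.0])}
        cfg = RegionConfig(ranges={"N": (1, 1), "ICL1": (2, 2)})
        model = StructureModel(residues=coords)
        axis = compute_axis(model, cfg)
        with pytest.raises(ValueError, match="TM"):
            tm_center_distance(model, axis, cfg)


class TestRegionConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RegionConfig(
            ranges={"N": (1, 10), "TM1": (11, 30), "ICL1": (31, 35)},
            excluded_ranges=((100, 120),),
            cterm_range=(200, 210),
            pocket_residues=frozenset({12, 13}),
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = RegionConfig.from_yaml(path)
        assert back == cfg

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            RegionConfig(ranges={"TM8": (1, 2)})

    def test_region_lookup_and_exclusion(self):
        cfg = RegionConfig(
            ranges={"N": (1, 5), "TM1": (6, 10)},
            excluded_ranges=((8, 9),),
            pocket_residues=frozenset({7}),
        )
        assert cfg.region_of(3) == "N"
        assert cfg.region_of(8) is None
        assert cfg.region_of(99) is None
        assert cfg.in_pocket(7) and not cfg.in_pocket(6)

    def test_packaged_cxcr4_config(self):
        from ckrdiv.datasets import cxcr4_region_config

        cfg = cxcr4_region_config()
        # contiguous coverage from the N-terminus to the C-terminal tail
        spans = sorted(cfg.ranges.values())
        assert spans[0][0] == 1
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert a2 == b1 + 1
        assert cfg.cterm_range == (303, 328)
        assert cfg.is_excluded(1100)          # lysozyme insert
        assert cfg.region_of(134) == "ICL2"   # DRY-motif arginine
        assert cfg.region_of(56) == "TM1"     # 1.50 anchor
        assert cfg.in_pocket(190)
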