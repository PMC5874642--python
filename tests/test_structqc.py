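"""Backbone dihedrals, PDB reading, and Ramachandran classification."""

import math

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral

from epiprof import structqc
from epiprof.structqc import (
    DihedralRecord,
    GeometryError,
    RamaRegions,
    classify_rama,
    dihedral,
    phi_psi,
    rama_summary,
    read_pdb_backbone,
)
from epiprof.synthetic_data import build_helix_coords, write_backbone_pdb

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.042   2.804   0.100  1.00  0.00           C
ATOM      6  C   ALA A   2       5.504   2.600   0.400  1.00  0.00           C
ATOM      7  N   ALA A   3       6.305   3.650   0.300  1.00  0.00           N
ATOM      8  CA  ALA A   3       7.751   3.600   0.500  1.00  0.00           C
ATOM      9  C   ALA A   3       8.401   4.950   0.700  1.00  0.00           C
END
"""


class TestPdbReading:
    def test_minimal_three_residues(self, tmp_path):
        f = tmp_path / "mini.pdb"
        f.write_text(MINIMAL_PDB)
        chain = read_pdb_backbone(f)
        assert len(chain) == 3
        assert all(r.complete for r in chain.residues)
        assert chain.breaks == frozenset()

    def test_round_trip_to_pdb_precision(self, tmp_path):
        f = tmp_path / "helix.pdb"
        built = build_helix_coords(10, -57, -47, path=f)
        chain = read_pdb_backbone(f)
        assert len(chain) == 10
        for res, built_res in zip(chain.residues, built):
            for attr, key in (("n", "N"), ("ca", "CA"), ("c", "C")):
                got = getattr(res, attr)
                assert np.allclose(got, built_res[key], atol=1e-3)

    def test_chain_break_recorded(self, tmp_path):
        built = build_helix_coords(8, -57, -47)
        # translate the second half 4 A away to break the peptide bond
        for res in built[4:]:
            for key in res:
                res[key] = res[key] + np.array([4.0, 0.0, 0.0])
        f = tmp_path / "broken.pdb"
        write_backbone_pdb(built, f)
        chain = read_pdb_backbone(f)
        assert 3 in chain.breaks
        records = phi_psi(chain)
        assert records[3].psi is None  # psi undefined before the break
        assert records[4].phi is None  # phi undefined after the break
        assert records[3].phi is not None and records[4].psi is not None

    def test_missing_chain_and_empty(self, tmp_path):
        f = tmp_path / "mini.pdb"
        f.write_text(MINIMAL_PDB)
        with pytest.raises(ValueError, match="chain 'B'"):
            read_pdb_backbone(f, chain_id="B")
        g = tmp_path / "empty.pdb"
        g.write_text("END\n")
        with pytest.raises(ValueError):
            read_pdb_backbone(g)


class TestDihedral:
    def test_cis_is_zero(self):
        a, b, c, d = [0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]
        assert dihedral(a, b, c, d) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        a, b, c, d = [0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]
        assert dihedral(a, b, c, d) == pytest.approx(180.0, abs=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_random_quadruples_match_independent_oracle(self):
        """1000 random quadruples against Biopython's vector implementation."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            theirs = math.degrees(calc_dihedral(*[Vector(*p) for p in pts]))
            if theirs <= -180.0:
                theirs += 360.0
            assert ours == pytest.approx(theirs, abs=1e-9)
            checked += 1

    def test_mirror_negates_torsions(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                fwd = dihedral(*pts)
            except GeometryError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            rev = dihedral(*mirrored)
            if abs(fwd) == pytest.approx(180.0, abs=1e-9):
                assert abs(rev) == pytest.approx(180.0, abs=1e-9)
            else:
                assert rev == pytest.approx(-fwd, abs=1e-9)


class TestPhiPsi:
    def test_two_residue_chain(self, tmp_path):
        f = tmp_path / "two.pdb"
        write_backbone_pdb(build_helix_coords(3, -60, -40)[:2], f)
        records = phi_psi(read_pdb_backbone(f))
        assert records[0].phi is None and records[0].psi is not None
        assert records[1].phi is not None and records[1].psi is None

    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-139.0, 135.0)])
    def test_build_then_measure(self, phi, psi):
        built = build_helix_coords(12, phi, psi)
        chain = structqc.BackboneChain(
            "A",
            tuple(
                structqc.BackboneResidue("ALA", i + 1, "", r["N"], r["CA"], r["C"])
                for i, r in enumerate(built)
            ),
        )
        records = phi_psi(chain)
        for rec in records[1:-1]:
            assert rec.phi == pytest.approx(phi, abs=1e-6)
            assert rec.psi == pytest.approx(psi, abs=1e-6)
            assert abs(rec.omega) == pytest.approx(180.0, abs=1e-6)

    def test_mirror_chain_negates_phi_psi(self):
        built = build_helix_coords(8, -57, -47)
        mirrored = [
            {k: v * np.array([1.0, 1.0, -1.0]) for k, v in res.items()}
            for res in built
        ]
        def to_chain(rs):
            return structqc.BackboneChain(
                "A",
                tuple(
                    structqc.BackboneResidue("GLY", i + 1, "", r["N"], r["CA"], r["C"])
                    for i, r in enumerate(rs)
                ),
            )
        fwd = phi_psi(to_chain(built))
        rev = phi_psi(to_chain(mirrored))
        for a, b in zip(fwd[1:-1], rev[1:-1]):
            assert b.phi == pytest.approx(-a.phi, abs=1e-9)
            assert b.psi == pytest.approx(-a.psi, abs=1e-9)


class TestRamaClassification:
    def test_canonical_alpha_point_favoured(self):
        assert RamaRegions().classify(-57, -47) == "favoured"

    def test_origin_is_outlier(self):
        assert RamaRegions().classify(0, 0) == "outlier"

    def test_matches_point_in_polygon_oracle(self):
        """Classification equals a shapely-free winding oracle on a grid."""
        from matplotlib.path import Path as MplPath

        regions = RamaRegions()
        polys = [("favoured", MplPath(p.exterior.coords)) for _, p in regions.favoured]
        polys += [("allowed", MplPath(p.exterior.coords)) for _, p in regions.allowed]

        def oracle(phi, psi):
            for cls in ("favoured", "allowed"):
                for c, path in polys:
                    if c == cls and path.contains_point((phi, psi), radius=1e-9):
                        return cls
            return "outlier"

        rng = np.random.default_rng(11)
        for _ in range(500):
            phi, psi = rng.uniform(-179.5, 179.5, size=2)
            assert regions.classify(phi, psi) == oracle(phi, psi)

    def test_boundary_point_gets_permissive_class(self):
        regions = RamaRegions()
        # (-45, -47) lies exactly on the alpha-favoured polygon edge
        assert regions.classify(-45.0, -47.0) == "favoured"
        # (-20, 30) lies on the broad-allowed edge, outside favoured polygons
        assert regions.classify(-20.0, 30.0) == "allowed"

    def test_classification_piecewise_constant(self):
        regions = RamaRegions()
        rng = np.random.default_rng(13)
        for _ in range(100):
            phi, psi = rng.uniform(-170, 170, size=2)
            cls = regions.classify(phi, psi)
            for dphi, dpsi in rng.normal(size=(5, 2)) * 1e-6:
                assert regions.classify(phi + dphi, psi + dpsi) == cls

    def test_undefined_angles_rejected(self):
        rec = DihedralRecord(0, "Ala1", None, -47.0)
        with pytest.raises(ValueError, match="undefined"):
            classify_rama(rec)


class TestSummary:
    def _rec(self, i, phi, psi):
        return DihedralRecord(i, f"Ala{i + 1}", phi, psi)

    def test_all_alpha_is_all_favoured(self):
        records = [self._rec(i, -57, -47) for i in range(20)]
        s = rama_summary(records)
        assert s.percentages == {"favoured": 100.0, "allowed": 0.0, "outlier": 0.0}
        assert s.outliers == ()

    def test_constructed_set_matches_hand_counts(self):
        """45 points with known memberships: 30 favoured, 10 allowed, 5 outlier."""
        records = (
            [self._rec(i, -57, -47) for i in range(15)]
            + [self._rec(15 + i, -139, 135) for i in range(15)]
            + [self._rec(30 + i, -30, -100) for i in range(10)]  # broad-allowed only
            + [self._rec(40 + i, 0, 0) for i in range(5)]
        )
        s = rama_summary(records)
        assert s.counts == {"favoured": 30, "allowed": 10, "outlier": 5}
        assert s.percentages["favoured"] == pytest.approx(100 * 30 / 45)
        assert len(s.outliers) == 5
        assert sum(s.percentages.values()) == pytest.approx(100.0, abs=0.05)

    def test_undefined_counted_separately(self):
        records = [self._rec(0, None, -47), self._rec(1, -57, -47)]
        s = rama_summary(records)
        assert s.n_classified == 1 and s.n_unclassified == 1

    def test_no_classifiable_residues_is_error(self):
        with pytest.raises(ValueError, match="classifiable"):
            rama_summary([self._rec(0, None, None)])
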