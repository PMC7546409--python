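"""Phantom geometry, label bookkeeping and tissue-model I/O."""

import numpy as np
import pytest
from scipy import ndimage

from pallisteer import anatomy as an
from pallisteer.anatomy import (
    ConsistencyError,
    Ellipsoid,
    GeometryError,
    PhantomSpec,
    build_pallidum_phantom,
    homogenize,
    read_tissue_model,
    write_tissue_model,
)

SMALL = PhantomSpec(
    domain_size_mm=(36.0, 36.0, 36.0),
    origin_mm=(-18.0, -18.0, -18.0),
    voxel_size_mm=0.25,
    gpe_ellipsoid=Ellipsoid((0.0, 0.0, 0.0), (8.0, 5.5, 5.0)),
    gpi_ellipsoid=Ellipsoid((0.0, 0.0, 0.0), (5.0, 3.0, 3.0)),
    lamina_thickness_mm=1.0,
)


@pytest.fixture(scope="module")
def small_model():
    return build_pallidum_phantom(SMALL)


def test_gpi_volume_matches_analytic_ellipsoid(small_model):
    """Voxel count of the GPi agrees with (4/3) pi abc within 5%."""
    expected = 4.0 / 3.0 * np.pi * 5.0 * 3.0 * 3.0
    vol = small_model.volumes_mm3()[an.GPI]
    assert abs(vol - expected) / expected < 0.05


def test_zero_lamina_thickness_yields_no_lamina_voxels():
    spec = PhantomSpec(lamina_thickness_mm=0.0)
    model = build_pallidum_phantom(spec)
    assert an.LAMINA not in model.volumes_mm3()


def test_phantom_deterministic(small_model):
    again = build_pallidum_phantom(SMALL)
    assert np.array_equal(small_model.label_grid, again.label_grid)


def test_labels_partition_domain(small_model):
    """Every voxel carries exactly one label; volumes sum to the domain."""
    total = sum(small_model.volumes_mm3().values())
    domain = np.prod(SMALL.domain_size_mm)
    assert total == pytest.approx(domain, abs=1e-9)


def test_lamina_separates_gpi_from_gpe(small_model):
    """No GPi voxel is 6-connected to a GPe voxel (lamina >= 2 voxels)."""
    gpi = small_model.label_grid == an.GPI
    dilated = ndimage.binary_dilation(
        gpi, structure=ndimage.generate_binary_structure(3, 1)
    )
    assert not np.any(dilated & (small_model.label_grid == an.GPE))


def test_structure_exceeding_domain_raises():
    bad = PhantomSpec(
        gpe_ellipsoid=Ellipsoid((0.0, 0.0, 0.0), (30.0, 6.0, 5.0)),
        gpi_ellipsoid=SMALL.gpi_ellipsoid,
    )
    with pytest.raises(GeometryError):
        build_pallidum_phantom(bad)


def test_homogenize_sets_internal_sigma(small_model):
    hom = homogenize(small_model, 0.3)
    for lab in hom.conductivity_table:
        if lab not in an.NON_TISSUE_LABELS:
            assert hom.conductivity_table[lab] == 0.3
    # electrode-hardware entries untouched
    assert hom.conductivity_table.get(an.INSULATION) == 0.0
    # geometry untouched, idempotent
    assert hom.volumes_mm3() == small_model.volumes_mm3()
    twice = homogenize(hom, 0.3)
    assert twice.conductivity_table == hom.conductivity_table
    with pytest.raises(ValueError):
        homogenize(small_model, -1.0)


def test_tissue_model_round_trip(small_model, tmp_path):
    write_tissue_model(small_model, tmp_path / "m.nii.gz", tmp_path / "m.tsv")
    back = read_tissue_model(tmp_path / "m.nii.gz", tmp_path / "m.tsv")
    assert np.array_equal(back.label_grid, small_model.label_grid)
    assert back.voxel_size_mm == pytest.approx(small_model.voxel_size_mm)
    assert np.allclose(back.origin_mm, small_model.origin_mm)
    for lab, sig in small_model.conductivity_table.items():
        assert back.conductivity_table[lab] == pytest.approx(sig)


def test_missing_table_label_is_reported(small_model, tmp_path):
    write_tissue_model(small_model, tmp_path / "m.nii.gz", tmp_path / "m.tsv")
    table = (tmp_path / "m.tsv").read_text().splitlines()
    kept = [row for row in table if not row.startswith(f"{an.GPI}\t")]
    (tmp_path / "short.tsv").write_text("\n".join(kept))
    with pytest.raises(ConsistencyError, match=str(an.GPI)):
        read_tissue_model(tmp_path / "m.nii.gz", tmp_path / "short.tsv")


def test_non_integer_volume_rejected(small_model, tmp_path):
    import nibabel as nib

    write_tissue_model(small_model, tmp_path / "m.nii.gz", tmp_path / "m.tsv")
    data = small_model.label_grid.astype(np.float32) + 0.25
    nib.save(nib.Nifti1Image(data, nib.load(tmp_path / "m.nii.gz").affine),
             tmp_path / "bad.nii.gz")
    with pytest.raises(ConsistencyError):
        read_tissue_model(tmp_path / "bad.nii.gz", tmp_path / "m.tsv")
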