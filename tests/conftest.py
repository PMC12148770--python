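import pytest

from dicom_unlink import make_4dct_study, make_mr_study, make_pet_study


@pytest.fixture
def mr_study(tmp_path):
    """3-series brain MR study (4 slices each) sharing one frame of reference."""
    root = tmp_path / "mr"
    manifest = make_mr_study(root, n_series=3, n_slices=4, seed=11)
    return root, manifest


@pytest.fixture
def fourdct_study(tmp_path):
    """10-phase 4DCT + free-breathing CT (2 slices each), one shared frame of reference."""
    root = tmp_path / "lung"
    manifest = make_4dct_study(
        root, n_phases=10, n_slices=2, include_free_breathing=True, seed=23
    )
    return root, manifest


@pytest.fixture
def mixed_study(tmp_path):
    """CT and MR series side by side in one folder, for modality-filter tests."""
    root = tmp_path / "mixed"
    make_4dct_study(
        root / "ct", n_phases=2, n_slices=2, include_free_breathing=False, seed=5
    )
    make_mr_study(root / "mr", n_series=2, n_slices=2, seed=6)
    make_pet_study(root / "pt", n_series=1, n_slices=2, seed=9)
    return root
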