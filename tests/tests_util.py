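"""Tiny shared constructors for tests."""

from tubulopy.cellseg import CellDetection


def make_cell(cell_id, x, y, cls="MAGE-A", hoechst=9000.0, roi_id=0):
    return CellDetection(
        cell_id=int(cell_id),
        image_id="t",
        roi_id=roi_id,
        x_um=float(x),
        y_um=float(y),
        nucleus_polygon=None,
        cell_polygon=None,
        nucleus_area_um2=50.0,
        cell_area_um2=150.0,
        nuclear_stats={"Hoechst": {"mean": float(hoechst), "sum": 0, "sd": 0, "max": 0}},
        cytosolic_stats={"Hoechst": {"mean": 0.0, "sum": 0, "sd": 0, "max": 0}},
        class_label=cls,
    )
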