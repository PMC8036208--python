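"""Regenerate the packaged material and cross-section data files."""
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from voxdose.materials import build_default_table, table_to_json
from voxdose.cross_sections import build_cross_section_table

root = pathlib.Path(__file__).resolve().parents[1] / "src" / "voxdose" / "data"
table = build_default_table()
(root / "materials.json").write_text(json.dumps(table_to_json(table), indent=1))
xs = build_cross_section_table(table)
(root / "cross_sections.csv").write_text(xs.to_csv())
print("wrote", root / "materials.json")
print("wrote", root / "cross_sections.csv")
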