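"""Generate a metadata template workbook from selected checklists.

Picks the MIxS soil environmental package plus a short-read sequencing
assay checklist from the bundled library and writes a multi-sheet
template workbook ready for sample registration.
"""

from pathlib import Path

from fairds import TemplateSpec, generate_template, load_default_library

library = load_default_library()
spec = TemplateSpec(
    library=library,
    packages=["mixs_soil", "ena_short_read_assay"],
    optional={"mixs_soil": ["depth", "ph", "soil_type"]},
    investigation_prefill={
        "investigation_identifier": "INV_example",
        "investigation_title": "Soil survey example",
    },
)
out = Path("template_soil.xlsx")
model = generate_template(spec, out)

print(f"wrote {out} with {len(model.sheets)} sheets:")
for sheet in model.sheets:
    print(f"  {sheet.name}: {len(sheet.headers)} columns "
          f"({len(sheet.mandatory)} mandatory)")
# Each sheet is one level of the Investigation -> Study -> Observation
# unit -> Sample -> Assay hierarchy; the column counts show how many
# attributes (core + checklist) the data producer is asked to record.
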