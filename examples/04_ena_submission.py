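"""Convert a validated project into ENA SRA XML submission documents.

Builds study/sample/experiment/run/submission XML (with MD5-checksummed
file blocks for the demo FASTQ files), validates the set structurally,
and writes the five documents to disk.
"""

import tempfile
from pathlib import Path

from fairds import (
    EnaOptions,
    FixtureConfig,
    build_submission,
    generate_fixtures,
    load_default_library,
    parse_workbook,
    validate_submission,
)

library = load_default_library()
workdir = Path(tempfile.mkdtemp())
fixtures = generate_fixtures(FixtureConfig(seed=42), workdir)
project, _ = parse_workbook(fixtures.workbook, library)

submission = build_submission(
    project, library,
    EnaOptions(checklist="ERC000024", center_name="Example Center",
               hold_date="2027-06-30"),
    data_dir=fixtures.data_dir,
)
paths = submission.write(workdir / "ena")
violations = validate_submission(submission)

print(f"study:      {len(submission.study_xml.findall('STUDY'))} STUDY")
print(f"sample:     {len(submission.sample_xml.findall('SAMPLE'))} SAMPLE")
print(f"experiment: "
      f"{len(submission.experiment_xml.findall('EXPERIMENT'))} EXPERIMENT")
print(f"run:        {len(submission.run_xml.findall('RUN'))} RUN")
print(f"violations: {len(violations)}")
for name, path in paths.items():
    print(f"  {name}.xml -> {path}")
# One SAMPLE per workbook sample, one EXPERIMENT per assay and one RUN
# per assay with data files; observation-unit attributes are folded into
# each descendant SAMPLE because the ENA model has no such level.
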