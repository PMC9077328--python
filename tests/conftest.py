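import csv

import pytest

from missensemap.variants import DEFAULT_COLUMNS

COLUMNS = [
    DEFAULT_COLUMNS["hgvs_p"],
    DEFAULT_COLUMNS["vep"],
    DEFAULT_COLUMNS["clinvar"],
    DEFAULT_COLUMNS["allele_count"],
    DEFAULT_COLUMNS["allele_number"],
    DEFAULT_COLUMNS["allele_frequency"],
]


def make_row(hgvs, vep="missense_variant", clinvar="", ac=1, an=100000, af=None):
    if af is None:
        af = ac / an
    return [hgvs, vep, clinvar, str(ac), str(an), repr(af)]


@pytest.fixture
def write_csv(tmp_path):
    """Write a gnomAD-dialect CSV from rows built with make_row()."""

    def _write(rows, name="variants.csv", columns=None):
        path = tmp_path / name
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns or COLUMNS)
            writer.writerows(rows)
        return path

    return _write
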