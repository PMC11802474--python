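<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>seqscope report</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1 { border-bottom: 2px solid #369; }
h2 { color: #369; margin-top: 1.6em; }
table { border-collapse: collapse; margin: 0.6em 0; }
td, th { border: 1px solid #bbb; padding: 0.25em 0.7em; text-align: right; }
th { background: #eef; }
td:first-child, th:first-child { text-align: left; }
.muted { color: #888; }
code { background: #f4f4f4; padding: 0 0.2em; }
</style>
</head>
<body>
<h1>seqscope quality-control report</h1>
<p class="muted">seqscope {{ r.metadata.version }} &mdash; schema {{ r.schema_version }}
&mdash; inputs: {% for f in r.metadata.inputs %}<code>{{ f }}</code>{% if not loop.last %}, {% endif %}{% endfor %}</p>

<h2>Summary</h2>
<table>
{% for key, value in r.summary.items() %}
<tr><td>{{ key }}</td><td>{{ value }}</td></tr>
{% endfor %}
</table>

<h2>Per-position profile</h2>
{% if r.per_position.bin_starts %}
<table>
<tr><th>position</th><th>coverage</th><th>A</th><th>C</th><th>G</th><th>T</th><th>N</th>
<th>mean Phred</th><th>Phred of mean error</th></tr>
{% for i in range(r.per_position.bin_starts | length) %}
{% if i < 25 or i % ((r.per_position.bin_starts | length // 50) + 1) == 0 %}
<tr><td>{{ r.per_position.bin_starts[i] }}</td>
<td>{{ r.per_position.coverage[i] }}</td>
{% for b in r.per_position.base_fractions[i] %}<td>{{ "%.3f" | format(b) if b is not none else "-" }}</td>{% endfor %}
<td>{{ "%.2f" | format(r.per_position.mean_phred[i]) if r.per_position.mean_phred[i] is not none else "-" }}</td>
<td>{{ "%.2f" | format(r.per_position.phred_of_mean_error[i]) if r.per_position.phred_of_mean_error[i] is not none else "-" }}</td></tr>
{% endif %}
{% endfor %}
</table>
{% else %}<p class="muted">no reads</p>{% endif %}

<h2>Per-read summaries</h2>
<p>Reads: {{ r.summary.total_reads }};
mean quality reported in both averaging modes (expected-error is the default;
the arithmetic Phred mean overestimates read quality).</p>
<table>
<tr><th>mode</th><th>reads &ge; Q15</th><th>reads &ge; Q20</th><th>reads &ge; Q30</th></tr>
<tr><td>expected error</td>
<td>{{ r.summary.reads_q15_expected_error }}</td>
<td>{{ r.summary.reads_q20_expected_error }}</td>
<td>{{ r.per_read.q_hist_expected_error[30:] | sum }}</td></tr>
<tr><td>arithmetic</td>
<td>{{ r.per_read.q_hist_arithmetic[15:] | sum }}</td>
<td>{{ r.summary.reads_q20_arithmetic }}</td>
<td>{{ r.summary.reads_q30_arithmetic }}</td></tr>
</table>

<h2>Adapter content (probe search)</h2>
<table>
<tr><th>probe</th><th>reads with hit</th><th>fraction</th></tr>
{% for label, row in r.adapter_content.probes.items() %}
<tr><td>{{ label }}</td><td>{{ row.reads_with_hit }}</td>
<td>{{ "%.5f" | format(row.fraction) }}</td></tr>
{% endfor %}
</table>

<h2>Insert sizes (paired-end overlap)</h2>
{% if r.insert_size %}
<p>Pairs: {{ r.insert_size.total_pairs }}; undetermined: {{ r.insert_size.undetermined }};
mode: {{ r.insert_size.mode }}; fraction with read-through adapter:
{{ "%.4f" | format(r.insert_size.adapter_fraction) }}</p>
{% else %}<p class="muted">single-end input: not applicable</p>{% endif %}

<h2>Duplication</h2>
<table>
<tr><td>estimated fraction remaining after deduplication</td>
<td>{{ r.duplication.remaining_fraction }}</td></tr>
<tr><td>estimated distinct sequences</td><td>{{ r.duplication.estimated_distinct }}</td></tr>
<tr><td>sampling depth (2^d)</td><td>{{ 2 ** r.duplication.depth }}</td></tr>
<tr><td>exact (no eviction)</td><td>{{ r.duplication.exact }}</td></tr>
</table>
{% if not r.duplication.exact %}
<p class="muted">eviction occurred: the multiplicity histogram is a hash-sample estimate.</p>
{% endif %}

<h2>Overrepresented fragments</h2>
<p>Sampled reads: {{ r.overrepresented.sampled_reads }};
distinct fragments stored: {{ r.overrepresented.distinct_fragments }}
{% if r.overrepresented.table_saturated %} (table saturated){% endif %}</p>
{% if r.overrepresented.fragments %}
<table>
<tr><th>fragment</th><th>count</th><th>fraction</th><th>best match</th><th>identity</th></tr>
{% for f in r.overrepresented.fragments %}
<tr><td><code>{{ f.sequence }}</code></td><td>{{ f.count }}</td>
<td>{{ "%.5f" | format(f.fraction) }}</td>
<td>{{ f.best_match_id if f.best_match_id else "unidentified" }}</td>
<td>{{ "%.4f" | format(f.identity) if f.identity is not none else "-" }}</td></tr>
{% endfor %}
</table>
{% else %}<p class="muted">none above threshold</p>{% endif %}

<h2>Illumina per-tile quality</h2>
{% if r.per_tile %}
<table>
<tr><th>tile</th><th>reads</th><th>mean Q (expected error)</th></tr>
{% for tile, count in r.per_tile.counts.items() %}
<tr><td>{{ tile }}</td><td>{{ count }}</td>
<td>{{ "%.2f" | format(r.per_tile.mean_quality[tile]) }}</td></tr>
{% endfor %}
</table>
{% else %}<p class="muted">no Casava-style tile information in read names</p>{% endif %}

<h2>ONT channels &amp; translocation speed</h2>
{% if r.ont %}
{% if r.ont.translocation_speed %}
<p>Translocation speed (bases/s): mean {{ "%.1f" | format(r.ont.translocation_speed.mean) }},
median {{ "%.1f" | format(r.ont.translocation_speed.median) }},
sd {{ "%.1f" | format(r.ont.translocation_speed.sd) }},
n={{ r.ont.translocation_speed.n }}</p>
{% endif %}
<p>Reads with channel info: {{ r.ont.reads_with_channel }}
over {{ r.ont.channel_activity | length }} channels</p>
{% else %}<p class="muted">no ONT metadata in input</p>{% endif %}

<h2>Warnings</h2>
{% if r.warnings %}
<ul>{% for w in r.warnings %}<li>{{ w }}</li>{% endfor %}</ul>
{% else %}<p class="muted">none</p>{% endif %}
</body>
</html>
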