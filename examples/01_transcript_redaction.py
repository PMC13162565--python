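"""Redact PHI in a diarized transcript.

Builds a small word-timestamped transcript with a planted patient name,
location and date, runs the rule engine over the flattened word table,
and prints the redacted rows. Each row keeps its original millisecond
interval — that alignment is what lets the audio stage scrub exactly the
words that were redacted here.
"""

from avdeid import synthetic
from avdeid.redact import apply_redaction, detect_phi
from avdeid.transcript import flatten_transcript

spec = synthetic.FixtureSpec(seed=0, duration_s=12.0)
transcript, planted = synthetic.gen_transcript(spec)
rules = synthetic.ruleset_for_plan(planted)

rows = flatten_transcript(transcript)
spans = detect_phi(rows, rules)
redacted, redaction_map = apply_redaction(rows, spans, rules)

print(f"{len(rows)} words, {len(spans)} PHI spans detected:")
for entry in redaction_map:
    print(f"  words {entry['word_start_index']}-{entry['word_end_index']}: "
          f"{entry['matched_text']!r} -> {entry['placeholder']}")

print("\nredacted rows around the first hit:")
lo = max(0, spans[0].word_start_index - 2)
print(redacted.iloc[lo : lo + 5][["index", "start_ms", "end_ms", "text"]]
      .to_string(index=False))
# Every placeholder row keeps its original timestamps; downstream audio
# scrubbing maps those intervals to tones.
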