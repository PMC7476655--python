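# One stop-word per line; lines starting with '#' are ignored.
# Deliberately small: function words only, never task content words.
a
am
an
and
are
at
be
for
i
in
is
it
its
my
of
on
or
that
the
this
to
was
were
with
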