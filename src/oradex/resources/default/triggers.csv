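phrase,source
secondary to,published_base
due to,published_base
caused by,published_base
cause of,published_base
attributed to,published_base
associated with,published_base
resulting in,published_base
resulted in,published_base
as a result of,published_base
side effect of,published_base
side effects of,published_base
adverse effect of,published_base
induced by,published_base
related to,published_base
complication of,published_base
contributed to,curated
contributing to,curated
thought to be due to,curated
felt to be due to,curated
thought to be secondary to,curated
felt to be secondary to,curated
likely due to,curated
likely secondary to,curated
possibly due to,curated
possibly secondary to,curated
presumed due to,curated
presumed secondary to,curated
attributable to,curated
in the setting of,curated
in the context of,curated
concerning for,curated
worrisome for,curated
suspicious for,curated
consistent with,curated
suggestive of,curated
subsequent,curated
subsequently,curated
developed after,curated
occurred after,curated
following administration of,curated
after administration of,curated
after receiving,curated
after starting,curated
after initiation of,curated
since starting,curated
since initiation of,curated
exacerbated by,curated
worsened by,curated
precipitated by,curated
triggered by,curated
provoked by,curated
aggravated by,curated
induced,curated
likely from,curated
likely related to,curated
possibly related to,curated
probably related to,curated
potentially related to,curated
temporally related to,curated
in association with,curated
likely caused by,curated
possibly caused by,curated
believed to be from,curated
suspected to be from,curated
suspected secondary to,curated
implicated in,curated
offending agent,curated
held due to,curated
discontinued due to,curated
stopped due to,curated
improved after stopping,curated
resolved after stopping,curated
complicated by,curated
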