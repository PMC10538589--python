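surface,generic,kind,class
morphine,morphine,generic,natural
ms contin,morphine,brand,natural
codeine,codeine,generic,natural
hydromorphone,hydromorphone,generic,semisynthetic
dilaudid,hydromorphone,brand,semisynthetic
oxycodone,oxycodone,generic,semisynthetic
percocet,oxycodone,brand,semisynthetic
oxycontin,oxycodone,brand,semisynthetic
roxicodone,oxycodone,brand,semisynthetic
hydrocodone,hydrocodone,generic,semisynthetic
vicodin,hydrocodone,brand,semisynthetic
norco,hydrocodone,brand,semisynthetic
oxymorphone,oxymorphone,generic,semisynthetic
opana,oxymorphone,brand,semisynthetic
buprenorphine,buprenorphine,generic,semisynthetic
suboxone,buprenorphine,brand,semisynthetic
fentanyl,fentanyl,generic,synthetic
duragesic,fentanyl,brand,synthetic
tramadol,tramadol,generic,synthetic
ultram,tramadol,brand,synthetic
methadone,methadone,generic,synthetic
dolophine,methadone,brand,synthetic
meperidine,meperidine,generic,synthetic
demerol,meperidine,brand,synthetic
tapentadol,tapentadol,generic,synthetic
nucynta,tapentadol,brand,synthetic
darvocet,propoxyphene,replaced_discontinued,synthetic
propoxyphene,propoxyphene,generic,synthetic
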