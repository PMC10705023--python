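word,category,season,phase_pre,phase_post,delta_min,p_label
chamomile,sleep_health,spring,23:39,23:04,-35,<0.0001
chamomile,sleep_health,autumn,23:00,23:30,30,<0.0001
emergency room,sleep_health,spring,02:16,01:40,-36,<0.0001
emergency room,sleep_health,autumn,01:10,02:07,57,<0.0001
insomnia,sleep_health,spring,02:18,01:19,-59,<0.0001
insomnia,sleep_health,autumn,01:14,02:11,57,<0.0001
melatonin,sleep_health,spring,00:49,00:13,-36,<0.0001
melatonin,sleep_health,autumn,00:14,00:46,32,<0.0001
sleep,sleep_health,spring,01:30,00:52,-38,<0.0001
sleep,sleep_health,autumn,00:43,01:23,40,<0.0001
stress,sleep_health,spring,00:45,00:20,-25,<0.0001
stress,sleep_health,autumn,00:13,00:45,32,<0.0001
painkiller,medication,spring,02:46,02:02,-44,<0.001
painkiller,medication,autumn,01:14,02:06,52,<0.0001
Xanax,medication,spring,00:41,00:11,-30,<0.0001
Xanax,medication,autumn,23:55,00:22,27,<0.0001
spa,random,spring,10:34,09:37,-57,<0.001
spa,random,autumn,09:40,10:39,59,0.004
taxi,random,spring,01:39,00:55,-44,<0.0001
taxi,random,autumn,00:51,01:42,51,<0.0001
weather forecast,random,spring,05:16,04:24,-52,<0.0001
weather forecast,random,autumn,04:08,05:01,53,<0.0001
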