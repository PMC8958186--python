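data,node,box,description,boxtext,tooltips,url,n
NA,node4,prevstud,Grey title box; Previous studies,Previous studies,Grey title box; Previous studies,prevstud.html,xxx
previous_studies,node5,box 1,Studies included in previous version of review,Studies included in previous version of review,Studies included in previous version of review,previous_studies.html,xxx
previous_reports,NA,box 1,Reports of studies included in previous version of review,Reports of studies included in previous version of review,NA,previous_reports.html,xxx
NA,node6,newstud,Yellow title box; Identification of new studies via databases and registers,Identification of new studies via databases and registers,Yellow title box; Identification of new studies via databases and registers,newstud.html,xxx
database_results,node7,box 2,Records identified from: Databases,Databases,Records identified from: Databases,database_results.html,xxx
register_results,NA,box 2,Records identified from: Registers,Registers,NA,NA,xxx
NA,node16,othstud,Grey title box; Identification of new studies via other methods,Identification of new studies via other methods,Grey title box; Identification of new studies via other methods,othstud.html,xxx
website_results,node17,box 11,Records identified from: Websites,Websites,Records identified from: Websites,website_results.html,xxx
organisation_results,NA,box 11,Records identified from: Organisations,Organisations,NA,NA,xxx
citations_results,NA,box 11,Records identified from: Citation searching,Citation searching,NA,NA,xxx
duplicates,node8,box 3,Duplicate records,Duplicate records,Duplicate records,duplicates.html,xxx
excluded_automatic,NA,box 3,Records marked as ineligible by automation tools,Records marked as ineligible by automation tools,NA,NA,xxx
excluded_other,NA,box 3,Records removed for other reasons,Records removed for other reasons,NA,NA,xxx
records_screened,node9,box 4,Records screened (databases and registers),Records screened,Records screened (databases and registers),records_screened.html,xxx
records_excluded,node10,box 5,Records excluded (databases and registers),Records excluded,Records excluded (databases and registers),records_excluded.html,xxx
dbr_sought_reports,node11,box 6,Reports sought for retrieval (databases and registers),Reports sought for retrieval,Reports sought for retrieval (databases and registers),dbr_sought_reports.html,xxx
dbr_notretrieved_reports,node12,box 7,Reports not retrieved (databases and registers),Reports not retrieved,Reports not retrieved (databases and registers),dbr_notretrieved_reports.html,xxx
other_sought_reports,node18,box 12,Reports sought for retrieval (other),Reports sought for retrieval,Reports sought for retrieval (other),other_sought_reports.html,xxx
other_notretrieved_reports,node19,box 13,Reports not retrieved (other),Reports not retrieved,Reports not retrieved (other),other_notretrieved_reports.html,xxx
dbr_assessed,node13,box 8,Reports assessed for eligibility (databases and registers),Reports assessed for eligibility,Reports assessed for eligibility (databases and registers),dbr_assessed.html,xxx
dbr_excluded,node14,box 9,"Reports excluded (databases and registers): [separate reasons and numbers using; e.g., Reason1, xxx; Reason2, xxx; Reason3, xxx",Reports excluded:,"Reports excluded (databases and registers): [separate reasons and numbers using; e.g., Reason1, xxx; Reason2, xxx; Reason3, xxx",dbrexcludedrecords.html,"Reason1, xxx; Reason2, xxx; Reason3, xxx"
other_assessed,node20,box 14,Reports assessed for eligibility (other),Reports assessed for eligibility,Reports assessed for eligibility (other),other_assessed.html,xxx
other_excluded,node21,box 15,"Reports excluded (other): [separate reasons and numbers using; e.g., Reason1, xxx; Reason2, xxx; Reason3, xxx",Reports excluded:,"Reports excluded (other): [separate reasons and numbers using; e.g., Reason1, xxx; Reason2, xxx; Reason3, xxx",other_excluded.html,"Reason1, xxx; Reason2, xxx; Reason3, xxx"
new_studies,node15,box 10,New studies included in review,New studies included in review,New studies included in review,new_studies.html,xxx
new_reports,NA,box 10,Reports of new included studies,Reports of new included studies,NA,NA,xxx
total_studies,node22,box 16,Total studies included in review,Total studies included in review,Total studies included in review,total_studies.html,xxx
total_reports,NA,box 16,Reports of total included studies,Reports of total included studies,NA,NA,xxx
identification,node1,identification,Blue identification box,Identification,Blue identification box,identification.html,xxx
screening,node2,screening,Blue screening box,Screening,Blue screening box,screening.html,xxx
included,node3,included,Blue included box,Included,Blue included box,included.html,xxx
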